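"""Generate a synthetic full-leg radiograph and measure its alignment.

Builds one varus phantom, runs the oracle measurement path (ground-truth
segmentation + landmarks through the real crop/projection/goniometry
code) and prints the five measured angles next to the generating values.
A measured mFAmTA below 180 deg means varus alignment; mMPTA/mLDFA/mLDTA
are the joint-line angles around 90 deg.
"""

from limbalign.phantom import PhantomSpec, generate_phantom
from limbalign.pipeline import measure_ground_truth

spec = PhantomSpec(knee_varus_valgus=4.0, plateau_obliquity=2.0, seed=1)
radiograph, truth = generate_phantom(spec)
report = measure_ground_truth(truth)[0]

print(f"leg side: {report.side}")
print(f"{'parameter':>10} {'measured':>10} {'generated':>10}")
for name, value in report.available().items():
    print(f"{name:>10} {value:10.4f} {truth.true_angles[name]:10.4f}")
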
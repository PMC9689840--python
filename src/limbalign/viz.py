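"""Overlay rendering: masks, landmarks, axes and angle labels on the image."""

from __future__ import annotations

import numpy as np

from .geometry import AlignmentReport, Unavailable


def save_overlay(path, image01: np.ndarray, reports: list[AlignmentReport],
                 landmark_sets=None) -> None:
    """Draw measured axes and angles over a radiograph and save as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = image01.shape
    fig, ax = plt.subplots(figsize=(w / 100.0, h / 100.0), dpi=100)
    ax.imshow(image01, cmap="gray", vmin=0, vmax=1)
    colors = {"femur_mech": "tab:red", "tibia_mech": "tab:blue",
              "femur_shaft": "tab:orange", "femoral_joint_line": "tab:green",
              "plateau_line": "tab:cyan", "ankle_line": "tab:purple"}
    for rep in reports:
        b = rep.intermediate
        if b is None:
            continue
        for name, color in colors.items():
            line = getattr(b, name)
            if isinstance(line, Unavailable):
                continue
            p, d = line.point, line.direction
            ext = 0.45 * h if name.endswith("mech") or name == "femur_shaft" else 60
            seg = np.array([p - ext * d, p + ext * d])
            ax.plot(seg[:, 0], seg[:, 1], color=color, lw=1.0)
        for cname in ("hip_center", "femoral_knee_center",
                      "tibial_knee_center", "ankle_center"):
            c = getattr(b, cname)
            if not isinstance(c, Unavailable):
                ax.plot(c[0], c[1], "o", ms=3, color="yellow")
        text = [f"{k}: {v:.1f}" for k, v in rep.available().items()]
        if text:
            x0 = 5 if rep.side == "right" else w - 120
            ax.text(x0, 20, "\n".join(text), color="white", fontsize=7,
                    va="top", family="monospace")
    if landmark_sets:
        for ls in landmark_sets:
            xy = ls.coords()
            ax.plot(xy[:, 0], xy[:, 1], ".", ms=2, color="lime")
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
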
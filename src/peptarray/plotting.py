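"""Plain plotting helpers (matplotlib required, imported lazily)."""
from __future__ import annotations

from .compare import OverlapReport
from .profile import BindingProfile


def plot_binding_profile(profile: BindingProfile, ax=None, **kwargs):
    """Median signal vs tile start position, dots joined by lines with
    replicate-SD error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = profile.points
    ax.errorbar(
        pts["start"], pts["median"], yerr=pts["sd"], marker="o", **kwargs
    )
    ax.set_xlabel("tile start (residue)")
    ax.set_ylabel("median signal (AU)")
    ax.set_title(f"{profile.accession} {profile.experiment_id}".strip())
    return ax


def plot_venn(report: OverlapReport, ax=None):
    """Schematic 2- or 3-circle Venn with exclusive region counts."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots()
    n = len(report.labels)
    centers = (
        [(-0.5, 0.0), (0.5, 0.0)]
        if n == 2
        else [(-0.5, -0.3), (0.5, -0.3), (0.0, 0.6)]
    )
    for (x, y), label in zip(centers, report.labels):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.3))
        ax.annotate(label, (x, y + 1.05), ha="center")
    text_pos = {
        frozenset([report.labels[0]]): (-1.0, 0.0),
        frozenset([report.labels[1]]): (1.0, 0.0),
        frozenset(report.labels[:2]): (0.0, -0.1),
    }
    if n == 3:
        text_pos.update(
            {
                frozenset([report.labels[2]]): (0.0, 1.0),
                frozenset([report.labels[0], report.labels[2]]): (-0.6, 0.5),
                frozenset([report.labels[1], report.labels[2]]): (0.6, 0.5),
                frozenset(report.labels): (0.0, 0.25),
            }
        )
    for key, (x, y) in text_pos.items():
        ax.annotate(str(report.regions[key]), (x, y), ha="center")
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-1.8, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
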
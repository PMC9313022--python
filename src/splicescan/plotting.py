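"""Optional profile-track plotting (requires the ``plot`` extra).

Renders a per-nucleotide score track with annotated regions shaded — the
familiar exon-profile figure style.  Kept out of the core: nothing in the
analysis pipeline imports matplotlib.
"""

from __future__ import annotations

from .profile import NucleotideProfile


def plot_profile_track(
    profile: NucleotideProfile,
    regions: dict[str, tuple[int, int]] | None = None,
    baseline: float | None = None,
    ax=None,
):
    """Plot the score track; shade *regions*; draw *baseline* dashed.

    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    positions = range(profile.offset, profile.offset + len(profile))
    ax.plot(list(positions), profile.scores, lw=0.8, color="black")
    for name, (a, b) in (regions or {}).items():
        ax.axvspan(a + profile.offset, b + profile.offset, alpha=0.2, label=name)
    if baseline is not None:
        ax.axhline(baseline, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("ESE/ESSseq score")
    if regions:
        ax.legend(fontsize="small")
    return ax
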
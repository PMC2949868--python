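"""Sliding-window nucleotide conservation score omega and peak detection.

The score for a window is the geometric mean of up to four components:

* ``omega0`` — mean pairwise nucleotide identity over all unordered pairs of
  core (database-derived) sequences;
* ``omega1..omega3`` — for each auxiliary species with sequence available
  (up to three, e.g. sea urchin / acorn worm / sea anemone genome hits), the
  *highest* identity between any core sequence and that species' sequence.

Windows are 20 nt wide by default, slide by one column, and each window's
value is assigned to its centre column so peaks line up with intron columns.
Local peaks are called in 51-column windows.  Positions where either
sequence has a gap are excluded from the identity denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

GAP = "-"


def window_identity(a: str, b: str, start: int, width: int) -> float:
    """Identity of aligned rows ``a``/``b`` over columns [start, start+width)
    (1-based start).  Gapped positions are excluded from the denominator; a
    window with no comparable positions scores 0.
    """
    if start < 1 or start + width - 1 > min(len(a), len(b)):
        raise IndexError(
            f"window [{start}, {start + width - 1}] out of bounds for length "
            f"{min(len(a), len(b))}"
        )
    matches = comparable = 0
    for i in range(start - 1, start - 1 + width):
        x, y = a[i], b[i]
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    return matches / comparable if comparable else 0.0


def omega_components(
    core: Sequence[str],
    aux: Optional[Sequence[Optional[str]]] = None,
    start: int = 1,
    width: int = 20,
) -> List[float]:
    """Components (omega0 first, then one per present auxiliary sequence).

    ``aux`` is a slot list of up to three aligned sequences; ``None`` slots
    contribute no component.
    """
    if len(core) < 2:
        raise ValueError("need >=2 core sequences for omega0")
    pair_vals = [
        window_identity(core[i], core[j], start, width)
        for i in range(len(core))
        for j in range(i + 1, len(core))
    ]
    comps = [sum(pair_vals) / len(pair_vals)]
    for aux_seq in aux or []:
        if aux_seq is None:
            continue
        comps.append(
            max(window_identity(c, aux_seq, start, width) for c in core)
        )
    return comps


def omega(components: Sequence[float]) -> float:
    """Geometric mean of the available components (0 if any component is 0)."""
    if not components:
        raise ValueError("no components")
    if any(c == 0 for c in components):
        return 0.0
    return math.exp(sum(math.log(c) for c in components) / len(components))


def detect_peaks(values: Sequence[float], peak_window: int = 51) -> List[int]:
    """Indices (0-based) of local peaks of ``values``.

    Position ``p`` is a peak iff its value is >= every value in the centred
    ``peak_window``-wide window and no earlier position inside the window
    ties it (leftmost-of-a-tied-run rule; boundaries use truncated windows).
    """
    if peak_window % 2 == 0:
        raise ValueError("peak window width must be odd")
    half = peak_window // 2
    n = len(values)
    peaks = []
    for p in range(n):
        lo, hi = max(0, p - half), min(n, p + half + 1)
        v = values[p]
        is_peak = True
        for q in range(lo, hi):
            if q == p:
                continue
            if values[q] > v or (values[q] == v and q < p):
                is_peak = False
                break
        if is_peak:
            peaks.append(p)
    return peaks


@dataclass
class ConservationProfile:
    """Per-column omega track over a codon alignment.

    ``columns[i]`` is the alignment column at the centre of window ``i``;
    ``components[k][i]`` holds component ``k`` (0 = omega0) for that window.
    """

    w: int
    peak_w: int
    columns: List[int]
    components: List[List[float]]
    omega_track: List[float]
    peak_columns: List[int] = field(default_factory=list)
    n_aux: int = 0

    def omega_at(self, column: int) -> float:
        try:
            return self.omega_track[self.columns.index(column)]
        except ValueError:
            raise KeyError(f"column {column} not on the profile grid")


def compute_profile(
    core: Sequence[str],
    aux: Optional[Sequence[Optional[str]]] = None,
    w: int = 20,
    peak_w: int = 51,
) -> ConservationProfile:
    """Slide a ``w``-wide window over the alignment and score every start."""
    length = min(len(s) for s in core)
    if length < w:
        raise ValueError(f"alignment length {length} shorter than window {w}")
    n_aux = sum(1 for a in aux or [] if a is not None)
    columns: List[int] = []
    per_comp: List[List[float]] = [[] for _ in range(1 + n_aux)]
    track: List[float] = []
    for start in range(1, length - w + 2):
        comps = omega_components(core, aux, start, w)
        for k, c in enumerate(comps):
            per_comp[k].append(c)
        track.append(omega(comps))
        columns.append(start + (w - 1) // 2)
    peaks_idx = detect_peaks(track, peak_w)
    return ConservationProfile(
        w=w,
        peak_w=peak_w,
        columns=columns,
        components=per_comp,
        omega_track=track,
        peak_columns=[columns[i] for i in peaks_idx],
        n_aux=n_aux,
    )


def export_plot_data(profile: ConservationProfile, intron_clusters=None) -> pd.DataFrame:
    """Tabular plot data: omega unscaled, auxiliary components halved for
    readability (presentation only — analysis values are untouched), plus
    peak and intron-occurrence marks.
    """
    data = {
        "column": profile.columns,
        "omega": profile.omega_track,
        "omega0": profile.components[0],
    }
    for k in range(1, len(profile.components)):
        data[f"omega{k}_plot"] = [v * 0.5 for v in profile.components[k]]
    df = pd.DataFrame(data)
    df["is_peak"] = df["column"].isin(set(profile.peak_columns))
    intron_cols = set()
    for cl in intron_clusters or []:
        intron_cols.add(cl.consensus_column)
    df["intron"] = df["column"].isin(intron_cols)
    return df


def plot_profile(profile: ConservationProfile, intron_clusters=None, path=None):
    """Render the stage-III diagnostic plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = export_plot_data(profile, intron_clusters)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(df["column"], df["omega"], color="black", lw=1, label="omega")
    colors = ["green", "blue", "red"]
    for k in range(1, len(profile.components)):
        ax.plot(
            df["column"],
            df[f"omega{k}_plot"],
            color=colors[(k - 1) % 3],
            lw=0.8,
            label=f"omega{k}/2",
        )
    for p in profile.peak_columns:
        ax.axvline(p, color="grey", ls=":", lw=0.6)
    for cl in intron_clusters or []:
        ax.plot([cl.consensus_column], [1.02], marker="v", color="k", ms=4)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("similarity")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
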
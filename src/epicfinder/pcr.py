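"""Scoring and summarising of EPIC PCR screening results.

Each (genus, intron) trial is graded on agarose-gel evidence into one of
four ordered categories:

* ``P`` (promising) — every individual gives a clean, not-too-faint product
  long enough to contain an intron of at least ~70 bp, with at most three
  fragments (three only if one is a constant band);
* ``I`` (intron-size amplicon) — an intron-sized product was seen but it was
  faint, multi-banded, or at least one individual failed;
* ``A`` (amplification) — products too short to contain a useful intron;
* ``null`` — no product in any individual.

``na`` marks untested combinations.  Results over protocols, individuals and
congeneric species pool to the *best* category (null < A < I < P).  On top
of the pooled intron x genus matrix the module computes per-genus summaries,
per-clade means of amplifying loci, "universal" introns (P or I in every
genus tested), correspondence-analysis coordinates, and the exact test
relating primer degeneracy to PCR outcome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CATEGORIES = ("null", "A", "I", "P")
_ORDER = {c: i for i, c in enumerate(CATEGORIES)}
NA = "na"


@dataclass
class Fragment:
    size: int
    intensity: str = "strong"  # "strong" | "faint"
    constant: bool = False

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("fragment size must be > 0")
        if self.intensity not in ("strong", "faint"):
            raise ValueError(f"unknown intensity {self.intensity!r}")


def classify(
    individuals: Sequence[Sequence[Fragment]],
    expected_size: Optional[int],
    min_intron: int = 70,
) -> str:
    """Grade one species x intron x primer-pair trial.

    ``individuals`` holds one fragment list per individual (empty list = no
    amplification).  A fragment is *intron-sized* when its size is at least
    ``expected_size + min_intron``; with the expected exon-only size unknown
    every fragment is treated as potentially intron-sized.
    """
    if not individuals:
        raise ValueError("at least one individual required")
    threshold = (expected_size + min_intron) if expected_size is not None else 0

    def intron_sized(fr: Fragment) -> bool:
        return fr.size >= threshold if threshold else True

    any_product = any(ind for ind in individuals)
    if not any_product:
        return "null"
    seen_intron = any(
        intron_sized(fr) for ind in individuals for fr in ind
    )
    if not seen_intron:
        return "A"

    # candidate for P: every individual must show a clean intron-sized product
    for ind in individuals:
        sized = [fr for fr in ind if intron_sized(fr)]
        if not sized:
            return "I"  # failed (or too short) in this individual
        if all(fr.intensity == "faint" for fr in sized):
            return "I"
        if len(ind) > 3:
            return "I"
        if len(ind) == 3 and not any(fr.constant for fr in ind):
            return "I"
    return "P"


def pool(categories: Iterable[str]) -> str:
    """Best category under null < A < I < P; all-na pools to na."""
    best = None
    saw_any = False
    for c in categories:
        saw_any = True
        if c == NA:
            continue
        if c not in _ORDER:
            raise ValueError(f"unknown category {c!r}")
        if best is None or _ORDER[c] > _ORDER[best]:
            best = c
    if not saw_any:
        raise ValueError("nothing to pool")
    return best if best is not None else NA


@dataclass
class PcrResultMatrix:
    """Intron x genus matrix of pooled categories.

    ``data`` is a DataFrame indexed by intron id (string), one column per
    genus, cells in {P, I, A, null, na}.  ``merge_groups`` lists intron ids
    later pooled into one row (the same intron recovered twice)."""

    data: pd.DataFrame
    merge_groups: List[List[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        valid = set(CATEGORIES) | {NA}
        bad = set(self.data.values.ravel()) - valid
        if bad:
            raise ValueError(f"invalid cell values: {sorted(bad)}")
        rows = set(self.data.index)
        for grp in self.merge_groups:
            missing = set(grp) - rows
            if missing:
                raise ValueError(f"merge group references unknown rows {missing}")

    @property
    def genera(self) -> List[str]:
        return list(self.data.columns)

    @property
    def intron_ids(self) -> List[str]:
        return list(self.data.index)

    def merged(self) -> "PcrResultMatrix":
        """Pool each merge group into one row (best category per genus)."""
        df = self.data.copy()
        for grp in self.merge_groups:
            pooled = df.loc[grp].apply(lambda col: pool(col.tolist()), axis=0)
            new_id = "+".join(grp)
            df = df.drop(index=grp)
            df.loc[new_id] = pooled
        return PcrResultMatrix(data=df, merge_groups=[])

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: Path) -> "PcrResultMatrix":
        merge_groups = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# merge:"):
                    merge_groups.append(
                        [x.strip() for x in line.split(":", 1)[1].split(",")]
                    )
        df = pd.read_csv(
            path, sep="\t", comment="#", index_col=0, dtype=str, keep_default_na=False
        )
        df.index = df.index.astype(str)
        df = df.replace("", "null")
        return cls(data=df, merge_groups=merge_groups)

    def to_tsv(self, path: Path) -> None:
        with open(path, "w") as fh:
            for grp in self.merge_groups:
                fh.write("# merge: " + ",".join(grp) + "\n")
            out = self.data.replace("null", "")
            out.index.name = "intron"
            out.to_csv(fh, sep="\t")


def summarize_by_genus(matrix: PcrResultMatrix) -> pd.DataFrame:
    """Per-genus counts of P, I, A, null, plus tested total and na count."""
    rows = []
    for genus in matrix.genera:
        col = matrix.data[genus]
        counts = {c: int((col == c).sum()) for c in CATEGORIES}
        n_na = int((col == NA).sum())
        rows.append(
            {
                "genus": genus,
                "P": counts["P"],
                "I": counts["I"],
                "A": counts["A"],
                "null": counts["null"],
                "total": len(col) - n_na,
                "na": n_na,
            }
        )
    return pd.DataFrame(rows).set_index("genus")


def clade_mean_amplifying(
    matrix: PcrResultMatrix,
    genus_to_clade: Dict[str, str],
    clades: Optional[Sequence[str]] = None,
    rounding: str = "exact",
) -> Dict[str, float]:
    """Mean number of amplifying (P + I) loci per genus within each clade."""
    if rounding not in ("exact", "nearest"):
        raise ValueError("rounding must be 'exact' or 'nearest'")
    summary = summarize_by_genus(matrix)
    means: Dict[str, float] = {}
    wanted = clades or sorted(set(genus_to_clade.values()))
    for clade in wanted:
        members = [g for g in matrix.genera if genus_to_clade.get(g) == clade]
        if not members:
            continue
        vals = [summary.loc[g, "P"] + summary.loc[g, "I"] for g in members]
        m = sum(vals) / len(vals)
        means[clade] = float(round(m)) if rounding == "nearest" else m
    return means


def find_universal_introns(matrix: PcrResultMatrix) -> List[str]:
    """Introns scored P or I in every genus where they were tested.

    Merge groups are applied first; rows tested in no genus never qualify.
    """
    merged = matrix.merged() if matrix.merge_groups else matrix
    out = []
    for intron in merged.intron_ids:
        row = merged.data.loc[intron]
        tested = row[row != NA]
        if len(tested) and tested.isin(["P", "I"]).all():
            out.append(intron)
    return out


# ---------------------------------------------------------------------------
# Correspondence analysis (Fig. 6 style: cells scored null=0, A=1, I=2, P=3)
# ---------------------------------------------------------------------------

DEFAULT_SCORE_MAP = {"null": 0, "A": 1, "I": 2, "P": 3}


def ca_coordinates(
    matrix: PcrResultMatrix,
    score_map: Optional[Dict[str, int]] = None,
    dims: int = 2,
    genera: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Principal coordinates of the genera (columns) from a correspondence
    analysis of the scored matrix.

    Rows/columns with zero sum are dropped with a warning; ``na`` cells score
    0.  Signs follow a deterministic, column-order-independent convention:
    the largest-magnitude coordinate of each dimension is made positive.
    """
    score_map = score_map or DEFAULT_SCORE_MAP
    cols = list(genera) if genera is not None else matrix.genera
    scored = matrix.data[cols].map(lambda c: score_map.get(c, 0)).astype(float)

    row_sums = scored.sum(axis=1)
    col_sums = scored.sum(axis=0)
    drop_rows = row_sums[row_sums == 0].index.tolist()
    drop_cols = col_sums[col_sums == 0].index.tolist()
    if drop_rows or drop_cols:
        warnings.warn(
            f"dropping zero-sum rows {drop_rows} and columns {drop_cols}"
        )
        scored = scored.drop(index=drop_rows, columns=drop_cols)
    n = scored.values.sum()
    if n <= 0:
        raise ValueError("scored matrix has no positive entries")

    P = scored.values / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(dims, len(sv))
    coords = (Vt[:k].T * sv[:k]) / np.sqrt(c)[:, None]
    for d in range(k):
        anchor = np.argmax(np.abs(coords[:, d]))
        if coords[anchor, d] < 0:
            coords[:, d] *= -1
    return pd.DataFrame(
        coords,
        index=scored.columns,
        columns=[f"dim{d + 1}" for d in range(k)],
    )


# ---------------------------------------------------------------------------
# Exact test on the degeneracy x outcome contingency table (Fig. 7 style)
# ---------------------------------------------------------------------------


def degeneracy_contingency_table(
    cases: Sequence[Tuple[str, int, int]], threshold: int = 6
) -> pd.DataFrame:
    """Build the 4 x 3 outcome x degeneracy-class table.

    Each case is (category, forward degeneracy, reverse degeneracy); the
    class is the number of the pair's primers with degeneracy strictly above
    ``threshold`` (0, 1 or 2).
    """
    table = pd.DataFrame(
        0, index=list(CATEGORIES), columns=[0, 1, 2], dtype=int
    )
    for category, deg_f, deg_r in cases:
        if deg_f <= 0 or deg_r <= 0:
            raise ValueError("primer degeneracy must be positive")
        if category not in _ORDER:
            raise ValueError(f"unknown category {category!r}")
        klass = int(deg_f > threshold) + int(deg_r > threshold)
        table.loc[category, klass] += 1
    return table


def _log_table_prob(cells: np.ndarray, lg_margins: float) -> float:
    return lg_margins - sum(math.lgamma(v + 1) for v in cells.ravel())


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(i, cols_left, current):
        if i == r - 1:
            last = cols_left
            if all(v >= 0 for v in last) and sum(last) == row_sums[-1]:
                yield current + [list(last)]
            return
        # enumerate row i summing to row_sums[i], bounded by cols_left
        def row_rec(j, remaining, row):
            if j == c - 1:
                if 0 <= remaining <= cols_left[j]:
                    yield row + [remaining]
                return
            for v in range(min(remaining, cols_left[j]) + 1):
                yield from row_rec(j + 1, remaining - v, row + [v])

        for row in row_rec(0, row_sums[i], []):
            new_left = [cl - v for cl, v in zip(cols_left, row)]
            yield from rec(i + 1, new_left, current + [row])

    yield from rec(0, list(col_sums), [])


def exact_test(
    table: pd.DataFrame,
    max_tables: int = 2_000_000,
    n_monte_carlo: int = 20_000,
    seed: int = 0,
) -> Dict[str, object]:
    """Fisher–Freeman–Halton exact test on an r x c table.

    Uses the probability-ordering criterion: p is the total null probability
    of margin-fixed tables no more probable than the observed one.  Falls
    back to a seeded Monte Carlo estimate (with standard error) when the
    enumeration would exceed ``max_tables`` tables.

    Returns dict with keys ``p``, ``method`` ("enumeration"|"monte_carlo"),
    and ``se`` (None for enumeration).
    """
    obs = table.values.astype(int)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.size == 0 or obs.sum() == 0:
        raise ValueError("empty contingency table")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = obs.sum()
    lg_margins = (
        sum(math.lgamma(v + 1) for v in row_sums)
        + sum(math.lgamma(v + 1) for v in col_sums)
        - math.lgamma(n + 1)
    )
    log_p_obs = _log_table_prob(obs, lg_margins)
    tol = 1e-9

    count = 0
    total = 0.0
    enumerable = True
    for cells in _enumerate_tables(list(row_sums), list(col_sums)):
        count += 1
        if count > max_tables:
            enumerable = False
            break
        lp = _log_table_prob(np.array(cells), lg_margins)
        if lp <= log_p_obs + tol:
            total += math.exp(lp)
    if enumerable:
        return {"p": min(total, 1.0), "method": "enumeration", "se": None}

    rng = np.random.default_rng(seed)
    # sample from the margin-fixed null by shuffling column labels
    col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    for _ in range(n_monte_carlo):
        rng.shuffle(col_labels)
        sampled = np.zeros_like(obs)
        start = 0
        for i, rs in enumerate(row_sums):
            lbls, cnts = np.unique(col_labels[start : start + rs], return_counts=True)
            sampled[i, lbls] = cnts
            start += rs
        if _log_table_prob(sampled, lg_margins) <= log_p_obs + tol:
            hits += 1
    p = hits / n_monte_carlo
    se = math.sqrt(max(p * (1 - p), 1.0 / n_monte_carlo) / n_monte_carlo)
    return {"p": p, "method": "monte_carlo", "se": se}


def degeneracy_contingency_test(
    cases: Sequence[Tuple[str, int, int]],
    threshold: int = 6,
    max_tables: int = 2_000_000,
    n_monte_carlo: int = 20_000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Contingency table plus exact-test result for degeneracy vs outcome."""
    table = degeneracy_contingency_table(cases, threshold)
    result = exact_test(
        table, max_tables=max_tables, n_monte_carlo=n_monte_carlo, seed=seed
    )
    return table, result
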
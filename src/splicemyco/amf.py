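"""Trouvelot-style arbuscular-mycorrhization indices and group statistics.

Each 1-cm root fragment receives a colonization class 0-5 (fraction of the
fragment colonized by fungal structures) and an arbuscule class A0-A3
(arbuscule richness within the colonized part). The class weights are the
MYCOCALC realisation of the Trouvelot scoring system:

    colonization:  0 -> 0, 1 -> 1, 2 -> 5, 3 -> 30, 4 -> 70, 5 -> 95  (%)
    arbuscules:    A0 -> 0, A1 -> 10, A2 -> 50, A3 -> 100             (%)

From N scored fragments with n_c fragments in class c:

    F = 100 (N - n0) / N            frequency of mycorrhiza in the root system
    M = sum_c w(c) n_c / N          colonization intensity of the root system
    m = M N / (N - n0)              intensity within colonized fragments
    mAi = 100 * [sum of w(c) over fragments in arbuscule class Ai] /
          ((N - n0) * m)            share of m carried by arbuscule class Ai
    a = (100 mA3 + 50 mA2 + 10 mA1) / 100   arbuscule abundance, colonized part
    A = a M / 100                   arbuscule abundance in the root system

Group comparisons use the Kruskal-Wallis rank test with a rank-based Fisher
LSD post hoc (significance threshold 0.01) and a two-sample Student t-test
(threshold 0.05) for pairwise designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

INTENSITY_WEIGHTS = {0: 0.0, 1: 1.0, 2: 5.0, 3: 30.0, 4: 70.0, 5: 95.0}
ARBUSCULE_WEIGHTS = {"A0": 0.0, "A1": 10.0, "A2": 50.0, "A3": 100.0}
ARBUSCULE_CLASSES = ("A0", "A1", "A2", "A3")


class ScoreError(ValueError):
    pass


class GroupError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentScore:
    """One root fragment's colonization (0-5) and arbuscule (A0-A3) classes."""

    plant_id: str
    colonization_class: int
    arbuscule_class: str

    def __post_init__(self) -> None:
        if self.colonization_class not in INTENSITY_WEIGHTS:
            raise ScoreError(
                f"colonization class {self.colonization_class!r} outside 0-5"
            )
        if self.arbuscule_class not in ARBUSCULE_WEIGHTS:
            raise ScoreError(f"arbuscule class {self.arbuscule_class!r}")
        if self.colonization_class == 0 and self.arbuscule_class != "A0":
            raise ScoreError(
                "an uncolonized fragment (class 0) cannot carry arbuscules"
            )


@dataclass(frozen=True)
class MycorrhizationIndices:
    """Trouvelot indices for one root system (all values in percent)."""

    F: float
    M: float
    m: float
    a: float
    A: float
    N: int
    class_counts: Mapping[int, int]
    mA: Mapping[str, float]  # mA1..mA3 shares of m


def compute_indices(fragments: Sequence[FragmentScore]) -> MycorrhizationIndices:
    """Trouvelot indices for one plant's scored fragments."""
    if not fragments:
        raise ScoreError("no fragments scored")
    N = len(fragments)
    class_counts = {c: 0 for c in INTENSITY_WEIGHTS}
    arb_weighted = {label: 0.0 for label in ARBUSCULE_CLASSES}
    for frag in fragments:
        class_counts[frag.colonization_class] += 1
        arb_weighted[frag.arbuscule_class] += INTENSITY_WEIGHTS[
            frag.colonization_class
        ]
    n0 = class_counts[0]
    F = 100.0 * (N - n0) / N
    M = sum(INTENSITY_WEIGHTS[c] * n for c, n in class_counts.items()) / N
    m = M * N / (N - n0) if n0 < N else 0.0
    if m > 0:
        mA = {
            label: arb_weighted[label] / (N - n0) * 100.0 / m
            for label in ("A1", "A2", "A3")
        }
    else:
        mA = {label: 0.0 for label in ("A1", "A2", "A3")}
    a = (100.0 * mA["A3"] + 50.0 * mA["A2"] + 10.0 * mA["A1"]) / 100.0
    A = a * M / 100.0
    return MycorrhizationIndices(
        F=F, M=M, m=m, a=a, A=A, N=N, class_counts=class_counts, mA=mA
    )


def read_fragment_scores(path: str | Path) -> pd.DataFrame:
    """Read a fragment score TSV (plant_id, fragment_id, colonization_class,
    arbuscule_class), validating every row; malformed rows are reported with
    their line number."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"plant_id", "colonization_class", "arbuscule_class"}
    missing = required - set(df.columns)
    if missing:
        raise ScoreError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                FragmentScore(
                    plant_id=str(row.plant_id),
                    colonization_class=int(row.colonization_class),
                    arbuscule_class=str(row.arbuscule_class),
                )
            )
        except (ScoreError, ValueError) as exc:
            raise ScoreError(f"{path}: line {i}: {exc}") from exc
    out = pd.DataFrame(
        {
            "plant_id": [r.plant_id for r in records],
            "colonization_class": [r.colonization_class for r in records],
            "arbuscule_class": [r.arbuscule_class for r in records],
        }
    )
    return out


def indices_by_plant(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-plant Trouvelot indices from a validated fragment score table."""
    rows = []
    for plant_id, group in scores.groupby("plant_id", sort=True):
        frags = [
            FragmentScore(str(plant_id), int(c), str(a))
            for c, a in zip(group["colonization_class"], group["arbuscule_class"])
        ]
        idx = compute_indices(frags)
        rows.append(
            {
                "plant_id": plant_id,
                "N": idx.N,
                "F": idx.F,
                "M": idx.M,
                "m": idx.m,
                "a": idx.a,
                "A": idx.A,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction.

    Returns (H, p) with p from the chi-square approximation on k-1 degrees of
    freedom. All-identical data is degenerate but defined: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise GroupError("Kruskal-Wallis needs at least two groups")
    if any(len(g) < 1 for g in groups):
        raise GroupError("every group needs at least one value")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: str
    group_j: str
    mean_rank_i: float
    mean_rank_j: float
    t: float
    p: float
    significant: bool


def fisher_lsd_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.01,
) -> list[PairwiseComparison]:
    """Fisher LSD pairwise comparisons on rank-transformed data.

    All observations are ranked jointly (midranks for ties); each pair of
    groups is compared by a t statistic on mean ranks with the pooled
    within-group rank variance (the ANOVA-on-ranks mean squared error) and
    N - k degrees of freedom. Pairs with p < ``alpha`` are flagged.
    """
    k = len(groups)
    if k < 2:
        raise GroupError("post hoc needs at least two groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    sizes = [len(g) for g in groups]
    if any(n < 1 for n in sizes):
        raise GroupError("every group needs at least one value")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(flat)
    n_total = len(flat)
    df = n_total - k
    if df < 1:
        raise GroupError("not enough observations for the post hoc test")

    group_ranks: list[np.ndarray] = []
    offset = 0
    for n in sizes:
        group_ranks.append(ranks[offset : offset + n])
        offset += n
    means = [float(r.mean()) for r in group_ranks]
    sse = sum(float(((r - m) ** 2).sum()) for r, m in zip(group_ranks, means))
    mse = sse / df

    out: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(mse * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0.0:
                t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
                p = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / se
                p = 2.0 * stats.t.sf(abs(t), df)
            out.append(
                PairwiseComparison(
                    group_i=labels[i],
                    group_j=labels[j],
                    mean_rank_i=means[i],
                    mean_rank_j=means[j],
                    t=float(t),
                    p=float(p),
                    significant=bool(p < alpha),
                )
            )
    return out


def student_t(
    group1: Sequence[float],
    group2: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample Student t-test (pooled variance by default; Welch optional).

    Zero pooled variance with equal means is degenerate but defined:
    t = 0, p = 1.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise GroupError("each group needs at least two values")
    if g1.var(ddof=1) == 0.0 and g2.var(ddof=1) == 0.0:
        if g1.mean() == g2.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)


def group_statistics(
    indices: pd.DataFrame,
    group_of: Mapping[str, str],
    index_columns: Iterable[str] = ("F", "M", "a", "A"),
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Kruskal-Wallis + rank LSD post hoc per index across plant groups.

    ``group_of`` maps plant_id to a group label. Returns a tidy table with an
    omnibus row and one row per pairwise comparison for each index.
    """
    labelled = indices.copy()
    try:
        labelled["group"] = [group_of[str(p)] for p in labelled["plant_id"]]
    except KeyError as exc:
        raise GroupError(f"plant {exc} has no group assignment") from exc
    group_names = sorted(labelled["group"].unique())
    if len(group_names) < 2:
        raise GroupError("need at least two groups")

    rows = []
    for col in index_columns:
        groups = [
            labelled.loc[labelled["group"] == g, col].to_numpy(dtype=float)
            for g in group_names
        ]
        h, p = kruskal_wallis(groups)
        rows.append(
            {
                "index": col, "test": "kruskal_wallis", "comparison": "omnibus",
                "statistic": h, "p": p, "significant": p < alpha,
            }
        )
        for cmp_row in fisher_lsd_posthoc(groups, labels=group_names, alpha=alpha):
            rows.append(
                {
                    "index": col,
                    "test": "rank_lsd",
                    "comparison": f"{cmp_row.group_i} vs {cmp_row.group_j}",
                    "statistic": cmp_row.t,
                    "p": cmp_row.p,
                    "significant": cmp_row.significant,
                }
            )
    return pd.DataFrame(rows)


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a plant_id -> group assignment TSV (columns plant_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"plant_id", "group"} <= set(df.columns):
        raise GroupError(f"{path}: needs plant_id and group columns")
    return dict(zip(df["plant_id"], df["group"]))
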
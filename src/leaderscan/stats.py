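"""Group-level statistics: per-class feature comparisons and resampling nulls.

Two questions are answered here.  First, do the translationally
down-regulated (inhibitor-responsive) genes differ from non-significant
genes in a leader feature (length, MFE, %GC, %C ...)?  That is a per-class
median table with a one-way ANOVA plus Tukey's pairwise comparisons
(Kruskal-Wallis co-reported, since lengths are heavy-tailed).  Second, is
the responsive group's pooled G-quadruplex density unusual?  That is judged
against an empirical null built from many equally sized groups of
transcripts drawn at random from the background catalog, summarised as a
z-score of the observed density against the null mean and SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class GroupComparison:
    """One feature compared across classes (medians + omnibus/pairwise p)."""

    feature: str
    n: dict[str, int]
    medians: dict[str, float]
    anova_f: float
    anova_p: float
    tukey_p: dict[str, float]  # "A|B" -> adjusted p (NaN when a class < 2)
    kruskal_p: float


@dataclass(frozen=True)
class ResamplingNull:
    """Empirical null for a group's pooled G4 density."""

    observed_density: float
    n_iterations: int
    group_size: int
    null_mean: float
    null_sd: float
    z: float
    seed: int
    null_values: tuple[float, ...] = field(repr=False, default=())


def compare_groups(
    features: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    feature: str,
) -> GroupComparison:
    """Compare one feature column across class labels keyed by gene id.

    Requires at least two classes with two or more members.  Pairs
    involving a singleton class get NaN Tukey p-values rather than
    failing the whole comparison.
    """
    labels = pd.Series(labels)
    df = features[["gene_id", feature]].dropna().copy()
    df["class_label"] = df["gene_id"].map(labels)
    df = df.dropna(subset=["class_label"])
    groups = {
        cls: sub[feature].to_numpy(float)
        for cls, sub in df.groupby("class_label")
    }
    big = {c: v for c, v in groups.items() if len(v) >= 2}
    if len(big) < 2:
        raise ValueError("need >= 2 classes with >= 2 members each")

    f, p = sps.f_oneway(*big.values())
    kw_p = sps.kruskal(*big.values()).pvalue if len(big) >= 2 else float("nan")

    tukey_p: dict[str, float] = {}
    sub = df[df["class_label"].isin(big)]
    if len(big) >= 2:
        res = pairwise_tukeyhsd(
            sub[feature].to_numpy(float), sub["class_label"].to_numpy()
        )
        pairs = list(combinations(res.groupsunique, 2))
        for (g1, g2), pv in zip(pairs, res.pvalues):
            tukey_p[f"{g1}|{g2}"] = float(pv)
    small = [c for c in groups if c not in big]
    for c in small:
        for other in groups:
            if other != c:
                tukey_p[f"{min(c, other)}|{max(c, other)}"] = float("nan")

    return GroupComparison(
        feature=feature,
        n={c: int(len(v)) for c, v in groups.items()},
        medians={c: float(np.median(v)) for c, v in groups.items()},
        anova_f=float(f),
        anova_p=float(p),
        tukey_p=tukey_p,
        kruskal_p=float(kw_p),
    )


def resampling_z(
    group_ids: Sequence[str],
    background: pd.DataFrame,
    n_iterations: int = 1000,
    seed: int = 0,
    exclude_group: bool = False,
) -> ResamplingNull:
    """z-score of a group's pooled G4 density against random same-size groups.

    ``background`` has one row per leader with columns transcript_id,
    g4_count, length.  Each of ``n_iterations`` draws samples
    ``len(group_ids)`` transcripts without replacement from the background
    and computes the pooled density (total regions / total nt x 1000); the
    observed group's density is standardised against the null mean and SD.
    ``exclude_group`` removes the observed transcripts from the sampling
    pool (both conventions are defensible; the default keeps them).
    """
    required = {"transcript_id", "g4_count", "length"}
    if not required <= set(background.columns):
        raise ValueError(f"background lacks columns {required - set(background.columns)}")
    bg = background.set_index("transcript_id")
    missing = [t for t in group_ids if t not in bg.index]
    if missing:
        raise ValueError(f"group transcripts absent from background: {missing[:5]}")

    obs = bg.loc[list(group_ids)]
    observed = 1000.0 * obs["g4_count"].sum() / obs["length"].sum()

    pool = bg.drop(index=list(group_ids)) if exclude_group else bg
    pool = pool.sort_index()  # draws depend only on seed, not input row order
    k = len(group_ids)
    if len(pool) < k:
        raise ValueError("background smaller than the observed group")
    counts = pool["g4_count"].to_numpy(float)
    lengths = pool["length"].to_numpy(float)

    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    for i in range(n_iterations):
        idx = rng.choice(len(pool), size=k, replace=False)
        null[i] = 1000.0 * counts[idx].sum() / lengths[idx].sum()
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: resampled densities are constant")
    return ResamplingNull(
        observed_density=float(observed),
        n_iterations=n_iterations,
        group_size=k,
        null_mean=mean,
        null_sd=sd,
        z=(float(observed) - mean) / sd,
        seed=seed,
        null_values=tuple(null.tolist()),
    )


def summary_report(
    comparisons: Sequence[GroupComparison],
    resampling: ResamplingNull | None = None,
) -> dict:
    """Machine-readable report covering all comparisons plus the G4 null."""
    report: dict = {
        "comparisons": [asdict(c) for c in comparisons],
    }
    if resampling is not None:
        d = asdict(resampling)
        d.pop("null_values")
        report["g4_resampling"] = d
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
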
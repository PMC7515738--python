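"""Per-leader sequence features: composition, MFE, and MFE corrections.

The feature panel per 5' leader comprises length, single-base and GC /
pyrimidine percentages, a positional GC profile, the global minimum free
energy (MFE) of the predicted optimal secondary structure, MFE per
nucleotide, a background-corrected MFE (residual against a length+GC linear
model fitted on a background leader set), and a 20-nt / 2-nt-step sliding
window MFE profile.

Thermodynamic folding is delegated to the ViennaRNA nearest-neighbor
implementation (Turner parameters, 37 C) behind the single ``mfe_global``
adapter; everything layered on top — windows, normalisation, correction —
lives here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from leaderscan.catalog import Leader

WINDOW_NT = 20
WINDOW_STEP = 2

_RNA_OK = set("ACGU")


def _to_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    if set(seq) - (_RNA_OK | {"N"}):
        bad = sorted(set(seq) - (_RNA_OK | {"N"}))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return seq


def composition(sequence: str) -> dict[str, float]:
    """Base percentages over non-N positions; pyrimidine = C + U."""
    seq = _to_rna(sequence)
    informative = [b for b in seq if b != "N"]
    if not informative:
        raise ValueError("composition undefined: empty or all-N sequence")
    n = len(informative)
    counts = {b: informative.count(b) for b in "ACGU"}
    pct = {f"pct_{b.lower()}": 100.0 * counts[b] / n for b in "ACGU"}
    pct["pct_gc"] = pct["pct_g"] + pct["pct_c"]
    pct["pct_pyrimidine"] = pct["pct_c"] + pct["pct_u"]
    return pct


def positional_gc_profile(sequence: str, n_bins: int = 10) -> list[float]:
    """GC% in near-equal contiguous bins along the leader.

    When the leader is shorter than ``n_bins`` the whole sequence falls in
    a single bin (degenerate profile).  Remainder positions are assigned to
    the 5'-most bins.
    """
    seq = _to_rna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < n_bins:
        n_bins = 1
    base, rem = divmod(len(seq), n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    out, pos = [], 0
    for size in sizes:
        chunk = seq[pos : pos + size]
        gc = sum(1 for b in chunk if b in "GC")
        denom = sum(1 for b in chunk if b != "N")
        out.append(100.0 * gc / denom if denom else float("nan"))
        pos += size
    return out


def mfe_global(sequence: str) -> float:
    """Minimum free energy (kcal/mol) of the optimal secondary structure.

    Nearest-neighbor model at 37 C via ViennaRNA; 0.0 when no structure is
    stable.  T is read as U.
    """
    import RNA  # deferred: keeps module importable for non-folding uses

    seq = _to_rna(sequence)
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    _, mfe = RNA.fold(seq)
    return float(mfe)


def mfe_per_nt(mfe: float, length: int) -> float:
    if length <= 0:
        raise ValueError("length must be positive")
    return mfe / length


def mfe_windows(
    sequence: str, window: int = WINDOW_NT, step: int = WINDOW_STEP
) -> list[float]:
    """MFE of each ``window``-nt substring advanced by ``step`` nt.

    Sequences shorter than the window give an empty profile.
    """
    seq = _to_rna(sequence)
    if len(seq) < window:
        return []
    return [
        mfe_global(seq[i : i + window])
        for i in range(0, len(seq) - window + 1, step)
    ]


@dataclass(frozen=True)
class BackgroundMfeModel:
    """Linear background expectation MFE ~ a + b1*length + b2*GC%."""

    intercept: float
    slope_length: float
    slope_gc: float
    n: int
    r_squared: float

    def predict(self, length: float, pct_gc: float) -> float:
        return self.intercept + self.slope_length * length + self.slope_gc * pct_gc


def fit_background_mfe(
    lengths: Sequence[float], pct_gc: Sequence[float], mfes: Sequence[float],
    min_n: int = 50,
) -> BackgroundMfeModel:
    """Least-squares fit of MFE on leader length and GC%.

    The corrected MFE of a leader is its residual from this background, so
    a more negative corrected value means more structure than expected for
    the leader's length and composition.
    """
    lengths = np.asarray(lengths, float)
    pct_gc = np.asarray(pct_gc, float)
    mfes = np.asarray(mfes, float)
    if len(mfes) < min_n:
        raise ValueError(f"background needs >= {min_n} leaders, got {len(mfes)}")
    for name, col in (("length", lengths), ("pct_gc", pct_gc)):
        if np.ptp(col) == 0:
            raise ValueError(f"degenerate background: column {name!r} is constant")
    X = sm.add_constant(np.column_stack([lengths, pct_gc]))
    fit = sm.OLS(mfes, X).fit()
    return BackgroundMfeModel(
        intercept=float(fit.params[0]),
        slope_length=float(fit.params[1]),
        slope_gc=float(fit.params[2]),
        n=len(mfes),
        r_squared=float(fit.rsquared),
    )


def mfe_corrected(
    mfe: float, length: float, pct_gc: float, model: BackgroundMfeModel
) -> float:
    """Observed minus background-predicted MFE (residual, kcal/mol)."""
    return mfe - model.predict(length, pct_gc)


def compute_feature_table(
    leaders: Iterable[Leader],
    include_mfe: bool = True,
    include_windows: bool = False,
    correct_mfe: bool = True,
) -> pd.DataFrame:
    """Feature panel for a set of leaders, one row per usable leader.

    Folding dominates runtime, so ``include_mfe=False`` skips all MFE
    columns for composition-only analyses (e.g. large simulations).  The
    corrected MFE uses the input set itself as background when it is large
    enough; otherwise the column is NaN.
    """
    rows = []
    for ld in leaders:
        if not ld.usable:
            continue
        row: dict[str, object] = {
            "transcript_id": ld.transcript_id,
            "gene_id": ld.gene_id,
            "length": ld.length,
        }
        row.update(composition(ld.sequence))
        if include_mfe:
            mfe = mfe_global(ld.sequence)
            row["mfe"] = mfe
            row["mfe_per_nt"] = mfe_per_nt(mfe, ld.length)
            if include_windows:
                row["window_mfe"] = mfe_windows(ld.sequence)
        rows.append(row)
    df = pd.DataFrame(rows)
    if include_mfe and correct_mfe and len(df) >= 50:
        model = fit_background_mfe(df["length"], df["pct_gc"], df["mfe"])
        df["mfe_corrected"] = [
            mfe_corrected(m, l, g, model)
            for m, l, g in zip(df["mfe"], df["length"], df["pct_gc"])
        ]
    return df


def write_window_profiles(df: pd.DataFrame, path) -> None:
    """Long-format TSV of window MFE profiles (1-based window starts)."""
    rows = []
    for _, r in df.iterrows():
        for i, v in enumerate(r.get("window_mfe") or []):
            rows.append(
                {
                    "transcript_id": r["transcript_id"],
                    "window_start_1based": 1 + i * WINDOW_STEP,
                    "mfe": v,
                }
            )
    pd.DataFrame(rows, columns=["transcript_id", "window_start_1based", "mfe"]).to_csv(
        path, sep="\t", index=False
    )
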
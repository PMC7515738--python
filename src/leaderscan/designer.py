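"""Constrained random reporter 5' leaders.

Generates synthetic 5' leader inserts of fixed length and user-specified
nucleotide composition, free of forbidden motifs (by default the ATG start
codon, scanned in both T and U spelling), and flanked by cloning sites
(NdeI upstream, MluI downstream).  The default panel reproduces a 21-
construct design: Short (24 nt) and Long (148 nt) categories crossed with
low-C / high-C / high-GC compositions, three constructs each, plus three
G-free negative controls.

Sequences are drawn position-by-position from the target composition and
rejected whole whenever a forbidden motif appears, an internal restriction
site would be created, or the realized composition drifts beyond tolerance;
whole-sequence rejection keeps the per-position distribution unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NDEI_SITE = "CATATG"
MLUI_SITE = "ACGCGT"

#: composition tolerance: fraction of length, but never under one base
COMPOSITION_TOL = 0.05

_BASES = "ACGT"


def _canonical(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class DesignSpec:
    """A reporter-leader design request."""

    length: int
    target_composition: Mapping[str, float]
    forbidden_motifs: tuple[str, ...] = ("ATG",)
    forbidden_bases: frozenset[str] = frozenset()
    flank_5prime: str = NDEI_SITE
    flank_3prime: str = MLUI_SITE
    n_sequences: int = 3
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        comp = {_canonical(b): float(f) for b, f in self.target_composition.items()}
        object.__setattr__(self, "target_composition", comp)
        object.__setattr__(
            self, "forbidden_motifs", tuple(_canonical(m) for m in self.forbidden_motifs)
        )
        object.__setattr__(
            self, "forbidden_bases", frozenset(_canonical(b) for b in self.forbidden_bases)
        )
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        if any(b not in _BASES for b in comp):
            raise ValueError(f"composition keys must be bases, got {list(comp)}")
        for b in self.forbidden_bases:
            if comp.get(b, 0.0) != 0.0:
                raise ValueError(f"forbidden base {b} has non-zero composition")
        longest = max((len(m) for m in self.forbidden_motifs), default=0)
        if self.length <= longest:
            raise ValueError(
                f"length {self.length} must exceed longest forbidden motif ({longest})"
            )

    @property
    def tolerance_counts(self) -> int:
        return max(1, int(np.floor(COMPOSITION_TOL * self.length)))


@dataclass(frozen=True)
class DesignedLeader:
    """A generated insert with flanks and realized features."""

    name: str
    insert: str
    full_sequence: str
    realized_composition: dict[str, float] = field(default_factory=dict)
    mfe: float = float("nan")
    attempts_used: int = 0


def _contains_forbidden(insert: str, spec: DesignSpec) -> bool:
    canon = _canonical(insert)
    for motif in spec.forbidden_motifs:
        if motif in canon:
            return True
    # internal cloning sites would break the construct at ligation
    for site in (spec.flank_5prime, spec.flank_3prime):
        if site and _canonical(site) in canon:
            return True
    return False


def _composition_ok(insert: str, spec: DesignSpec) -> bool:
    tol = spec.tolerance_counts
    canon = _canonical(insert)
    for b, frac in spec.target_composition.items():
        if abs(canon.count(b) - frac * spec.length) > tol:
            return False
    return True


def generate_insert(
    spec: DesignSpec, rng: np.random.Generator, name: str = "insert"
) -> DesignedLeader:
    """Draw one insert satisfying every constraint (rejection sampling).

    Raises ``RuntimeError`` with an acceptance-rate estimate when
    ``spec.max_attempts`` draws all fail.
    """
    bases = [b for b in _BASES if spec.target_composition.get(b, 0.0) > 0]
    probs = np.array([spec.target_composition[b] for b in bases])
    probs = probs / probs.sum()
    for attempt in range(1, spec.max_attempts + 1):
        draw = rng.choice(len(bases), size=spec.length, p=probs)
        insert = "".join(bases[i] for i in draw)
        if _contains_forbidden(insert, spec):
            continue
        if not _composition_ok(insert, spec):
            continue
        return DesignedLeader(
            name=name,
            insert=insert,
            full_sequence=add_flanks(insert, spec),
            realized_composition={
                b: 100.0 * insert.count(b) / spec.length for b in _BASES
            },
            attempts_used=attempt,
        )
    raise RuntimeError(
        f"no valid insert in {spec.max_attempts} attempts "
        f"(estimated acceptance rate < {1 / spec.max_attempts:.2e}); "
        "relax the composition tolerance or forbidden motifs"
    )


def add_flanks(insert: str, spec: DesignSpec) -> str:
    """Attach cloning flanks; rejects inserts carrying an internal site.

    The ATG prohibition applies to the insert only — the upstream NdeI
    site (CATATG) itself ends in ATG by design.
    """
    canon = _canonical(insert)
    for site in (spec.flank_5prime, spec.flank_3prime):
        if site and _canonical(site) in canon:
            raise ValueError(f"INTERNAL_SITE: insert contains restriction site {site}")
    return spec.flank_5prime + insert + spec.flank_3prime


# Default panel: Short/Long crossed with three composition regimes.  The
# numeric composition targets are this package's own calibration of the
# low-C / high-C / high-GC strata (low-C ~15% C at ~50% GC; high-C ~35% C
# at ~50% GC; high-GC ~35% C at ~70% GC); edit via design_category_panel's
# ``categories`` argument or the shipped YAML config.
DEFAULT_COMPOSITIONS: dict[str, dict[str, float]] = {
    "LoC": {"A": 0.30, "C": 0.15, "G": 0.35, "T": 0.20},
    "HiC": {"A": 0.25, "C": 0.35, "G": 0.15, "T": 0.25},
    "HiGC": {"A": 0.15, "C": 0.35, "G": 0.35, "T": 0.15},
}
SHORT_LENGTH = 24
LONG_LENGTH = 148

DEFAULT_CONTROLS: dict[str, dict[str, float]] = {
    # G-free negative controls (no G -> no G-quadruplex propensity)
    "CAU": {"A": 0.34, "C": 0.33, "T": 0.33},
    "CA": {"A": 0.50, "C": 0.50},
}


def default_categories() -> dict[str, DesignSpec]:
    """Six category specs (Short/Long x LoC/HiC/HiGC), three inserts each."""
    cats: dict[str, DesignSpec] = {}
    for prefix, length in (("Short", SHORT_LENGTH), ("Long", LONG_LENGTH)):
        for comp_name, comp in DEFAULT_COMPOSITIONS.items():
            cats[f"{prefix}-{comp_name}"] = DesignSpec(
                length=length, target_composition=comp
            )
    return cats


def default_controls() -> dict[str, DesignSpec]:
    """Three G-free control specs: CAU-1, CA-1, CA-2 (long inserts)."""
    return {
        "CAU-1": DesignSpec(
            length=LONG_LENGTH,
            target_composition=DEFAULT_CONTROLS["CAU"],
            forbidden_bases=frozenset({"G"}),
            n_sequences=1,
        ),
        "CA-1": DesignSpec(
            length=LONG_LENGTH,
            target_composition=DEFAULT_CONTROLS["CA"],
            forbidden_bases=frozenset({"G"}),
            n_sequences=1,
        ),
        "CA-2": DesignSpec(
            length=LONG_LENGTH,
            target_composition=DEFAULT_CONTROLS["CA"],
            forbidden_bases=frozenset({"G"}),
            n_sequences=1,
        ),
    }


def design_category_panel(
    categories: Mapping[str, DesignSpec] | None = None,
    controls: Mapping[str, DesignSpec] | None = None,
    seed: int = 0,
    annotate_mfe: bool = True,
) -> list[DesignedLeader]:
    """Generate the full reporter panel (default 6x3 + 3 controls = 21).

    Within a category the three inserts must differ; a fixed seed gives a
    bit-identical panel.  When ``annotate_mfe`` each insert's MFE is
    computed and attached.
    """
    if categories is None:
        categories = default_categories()
    if controls is None:
        controls = default_controls()
    rng = np.random.default_rng(seed)
    panel: list[DesignedLeader] = []

    def _emit(name: str, spec: DesignSpec, count: int) -> None:
        seen: set[str] = set()
        for i in range(1, count + 1):
            for _ in range(spec.max_attempts):
                cand = generate_insert(
                    spec, rng, name=f"{name}-{i}" if count > 1 else name
                )
                if cand.insert not in seen:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError(f"could not draw distinct inserts for {name}")
            seen.add(cand.insert)
            panel.append(cand)

    for name, spec in categories.items():
        _emit(name, spec, spec.n_sequences)
    for name, spec in controls.items():
        _emit(name, spec, 1)

    if annotate_mfe:
        from leaderscan.features import mfe_global

        panel = [
            DesignedLeader(
                name=d.name,
                insert=d.insert,
                full_sequence=d.full_sequence,
                realized_composition=d.realized_composition,
                mfe=mfe_global(d.insert),
                attempts_used=d.attempts_used,
            )
            for d in panel
        ]
    return panel


def load_panel_yaml(
    path: str | Path,
) -> tuple[dict[str, DesignSpec], dict[str, DesignSpec]]:
    """Read category/control DesignSpecs from an editable YAML config.

    Schema: top-level ``categories`` and ``controls`` maps; each entry has
    ``length``, ``composition`` (base -> fraction) and optionally
    ``n_sequences``, ``forbidden_motifs``, ``forbidden_bases``.
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())

    def _spec(entry: Mapping) -> DesignSpec:
        return DesignSpec(
            length=int(entry["length"]),
            target_composition=entry["composition"],
            forbidden_motifs=tuple(entry.get("forbidden_motifs", ("ATG",))),
            forbidden_bases=frozenset(entry.get("forbidden_bases", ())),
            n_sequences=int(entry.get("n_sequences", 3)),
        )

    categories = {name: _spec(e) for name, e in (cfg.get("categories") or {}).items()}
    controls = {name: _spec(e) for name, e in (cfg.get("controls") or {}).items()}
    return categories, controls


def write_panel(panel: Iterable[DesignedLeader], out_dir: str | Path) -> None:
    """FASTA of full sequences plus an annotation TSV."""
    panel = list(panel)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "designed_leaders.fa", "w") as fh:
        for d in panel:
            fh.write(f">{d.name}\n{d.full_sequence}\n")
    rows = [
        {
            "name": d.name,
            "length": len(d.insert),
            "pct_gc": d.realized_composition.get("G", 0.0)
            + d.realized_composition.get("C", 0.0),
            "pct_c": d.realized_composition.get("C", 0.0),
            "mfe": d.mfe,
            "attempts": d.attempts_used,
        }
        for d in panel
    ]
    pd.DataFrame(rows).to_csv(out_dir / "designed_leaders.tsv", sep="\t", index=False)
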
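"""Synthetic study generator: toy transcriptome + counts with planted effects.

Emulates the statistical structure the leader-feature analysis assumes: a
transcriptome whose genes fall into two 5'-leader regimes — a small
"responsive" regime with long, C-rich, G4-seeded leaders and a "background"
regime with short plainer leaders — plus matched ribosome-profiling /
RNA-seq negative-binomial count tables in which a translation-efficiency
decrease is planted only in the responsive regime under treatment.

Defaults mirror the study conditions the pipeline is meant to recover:
leader length medians 363 nt (responsive) vs 138 nt (background), %C 35 vs
31.5, %GC 54.2 vs 52.1, a -1 log2 TE shift, and three replicates per
condition.  Every output is a plain-text file in the same dialect as the
real-data inputs (transcript FASTA, transcript-space GTF, APPRIS and TPM
TSVs, long-format counts TSV), so every other module consumes them without
special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from leaderscan.catalog import TranscriptRecord

#: planted G-quadruplex block (telomere-like G3 repeats, DNA spelling)
G4_BLOCK = "GGGTTAGGGTTAGGGTTAGGGTTAG"

RESPONSIVE = "responsive"
BACKGROUND = "background"

# Regime base compositions (A, C, G, T).  C and GC levels follow the
# medians the analysis is expected to report; A/T split the remainder.
_COMP_RESPONSIVE = {"A": 0.2293, "C": 0.3505, "G": 0.1910, "T": 0.2292}
_COMP_BACKGROUND = {"A": 0.2398, "C": 0.3148, "G": 0.2057, "T": 0.2397}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study (defaults = the emulated conditions)."""

    n_genes: int = 2000
    fraction_responsive: float = 0.10
    leader_median_responsive: float = 363.0
    leader_median_background: float = 138.0
    leader_log_sd: float = 0.6
    comp_responsive: dict = field(default_factory=lambda: dict(_COMP_RESPONSIVE))
    comp_background: dict = field(default_factory=lambda: dict(_COMP_BACKGROUND))
    g4_rate_responsive: float = 1.2  # planted blocks per 1000 leader nt
    g4_rate_background: float = 0.15
    te_effect_log2: float = -1.0
    replicates: int = 4
    dispersion: float = 0.005
    cds_median: float = 900.0
    cds_log_sd: float = 0.4
    lib_rna: float = 2_000_000.0
    lib_ribo: float = 5_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction_responsive < 1:
            raise ValueError("fraction_responsive must be in (0, 1)")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        for comp in (self.comp_responsive, self.comp_background):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"regime composition sums to {sum(comp.values())}")


@dataclass
class SimulatedStudy:
    """In-memory result of ``simulate_transcriptome``."""

    records: list[TranscriptRecord]
    truth: pd.DataFrame  # gene_id, transcript_id, regime, leader_length, ...
    config: SimulationConfig


def _lognormal_lengths(
    rng: np.random.Generator, n: int, median: float, log_sd: float, minimum: int = 25
) -> np.ndarray:
    draw = rng.lognormal(mean=np.log(median), sigma=log_sd, size=n)
    return np.maximum(np.round(draw).astype(int), minimum)


def _random_seq(rng: np.random.Generator, length: int, comp: dict[str, float]) -> str:
    bases = sorted(comp)
    probs = np.array([comp[b] for b in bases])
    idx = rng.choice(len(bases), size=length, p=probs / probs.sum())
    return "".join(bases[i] for i in idx)


def _plant_g4(rng: np.random.Generator, leader: str, rate_per_kb: float) -> tuple[str, int]:
    """Overwrite random stretches with G4 blocks; Poisson(rate x len/1000)."""
    if len(leader) <= len(G4_BLOCK):
        return leader, 0
    k = int(rng.poisson(rate_per_kb * len(leader) / 1000.0))
    seq = list(leader)
    planted = 0
    for _ in range(k):
        pos = int(rng.integers(0, len(leader) - len(G4_BLOCK)))
        seq[pos : pos + len(G4_BLOCK)] = G4_BLOCK
        planted += 1
    return "".join(seq), planted


def _make_cds(rng: np.random.Generator, length: int) -> str:
    length = max(3 * (length // 3), 9)
    body = _random_seq(rng, length - 6, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
    return "ATG" + body + "TAA"


def simulate_transcriptome(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedStudy:
    """Draw the toy transcriptome; optionally write the four input files.

    Each gene gets one to three isoforms; the first is APPRIS-principal and
    carries the regime's leader.  Alternative isoforms reuse a truncated
    leader at lower TPM.  FASTA ids carry a ``.1`` version suffix while the
    GTF ids do not, exercising version-tolerant matching downstream.
    """
    rng = np.random.default_rng([config.seed, 101])
    n_resp = int(round(config.n_genes * config.fraction_responsive))
    regimes = np.array(
        [RESPONSIVE] * n_resp + [BACKGROUND] * (config.n_genes - n_resp)
    )
    rng.shuffle(regimes)

    records: list[TranscriptRecord] = []
    truth_rows = []
    for g in range(config.n_genes):
        gid = f"GSYN{g + 1:05d}"
        regime = regimes[g]
        if regime == RESPONSIVE:
            median, comp, g4_rate = (
                config.leader_median_responsive,
                config.comp_responsive,
                config.g4_rate_responsive,
            )
        else:
            median, comp, g4_rate = (
                config.leader_median_background,
                config.comp_background,
                config.g4_rate_background,
            )
        leader_len = int(
            _lognormal_lengths(rng, 1, median, config.leader_log_sd)[0]
        )
        leader = _random_seq(rng, leader_len, comp)
        leader, n_blocks = _plant_g4(rng, leader, g4_rate)
        cds_len = int(
            _lognormal_lengths(rng, 1, config.cds_median, config.cds_log_sd, 60)[0]
        )
        cds = _make_cds(rng, cds_len)
        tpm = float(rng.lognormal(np.log(10.0), 1.0))

        principal_tid = f"TSYN{g + 1:05d}"
        records.append(
            TranscriptRecord(
                transcript_id=principal_tid,
                gene_id=gid,
                sequence=leader + cds,
                cds_start=len(leader) + 1,
                appris_tag="PRINCIPAL",
                tpm=tpm,
            )
        )
        n_iso = int(rng.integers(1, 4))
        for j in range(2, n_iso + 1):
            alt_leader = leader[len(leader) // 2 :]
            records.append(
                TranscriptRecord(
                    transcript_id=f"TSYN{g + 1:05d}A{j}",
                    gene_id=gid,
                    sequence=alt_leader + cds,
                    cds_start=len(alt_leader) + 1,
                    appris_tag="ALTERNATIVE",
                    tpm=tpm * float(rng.uniform(0.05, 0.5)),
                )
            )
        truth_rows.append(
            {
                "gene_id": gid,
                "transcript_id": principal_tid,
                "regime": regime,
                "leader_length": len(leader),
                "n_g4_blocks": n_blocks,
                "cds_length": len(cds),
                "tpm": tpm,
            }
        )

    truth = pd.DataFrame(truth_rows)
    study = SimulatedStudy(records=records, truth=truth, config=config)
    if out_dir is not None:
        write_study_inputs(study, out_dir)
    return study


def write_study_inputs(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA / GTF / APPRIS TSV / TPM TSV in the real-data dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "transcripts.fa",
        "gtf": out / "annotation.gtf",
        "appris": out / "appris.tsv",
        "tpm": out / "tpm.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for rec in study.records:
            fh.write(f">{rec.transcript_id}.1\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")
    with open(paths["gtf"], "w") as fh:
        for rec in study.records:
            attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
            L = len(rec.sequence)
            fh.write(
                f"{rec.transcript_id}\tleaderscan_sim\texon\t1\t{L}\t.\t+\t.\t{attrs}\n"
            )
            if rec.cds_start is not None:
                fh.write(
                    f"{rec.transcript_id}\tleaderscan_sim\tCDS\t{rec.cds_start}\t{L - 3}"
                    f"\t.\t+\t0\t{attrs}\n"
                )
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in study.records],
            "tag": [
                "PRINCIPAL:1" if r.appris_tag == "PRINCIPAL" else "ALTERNATIVE:2"
                for r in study.records
            ],
        }
    ).to_csv(paths["appris"], sep="\t", index=False)
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in study.records],
            "tpm": [r.tpm for r in study.records],
        }
    ).to_csv(paths["tpm"], sep="\t", index=False)
    return paths


def _nb(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    study: SimulatedStudy, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Matched Ribo/RNA count tables with the planted TE effect.

    RNA counts are NB with mean proportional to TPM x CDS length scaled to
    the RNA library size; Ribo counts add a per-gene baseline TE and, for
    responsive genes in the treated condition only, the configured log2 TE
    shift.  Long format: gene_id, condition, replicate, ribo, rna.
    """
    cfg = study.config
    rng = np.random.default_rng([cfg.seed, 202])
    truth = study.truth
    n = len(truth)

    weight = truth["tpm"].to_numpy() * truth["cds_length"].to_numpy()
    rna_mu = weight / weight.sum() * cfg.lib_rna
    base_te = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    ribo_weight = weight * base_te
    ribo_mu0 = ribo_weight / ribo_weight.sum() * cfg.lib_ribo
    effect = np.where(
        truth["regime"].to_numpy() == RESPONSIVE, 2.0 ** cfg.te_effect_log2, 1.0
    )

    rows = []
    for cond, te_mult in (("vehicle", np.ones(n)), ("treated", effect)):
        for rep in range(1, cfg.replicates + 1):
            rna = _nb(rng, rna_mu, cfg.dispersion)
            ribo = _nb(rng, ribo_mu0 * te_mult, cfg.dispersion)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": truth["gene_id"],
                        "condition": cond,
                        "replicate": rep,
                        "ribo": ribo,
                        "rna": rna,
                    }
                )
            )
    counts = pd.concat(rows, ignore_index=True)
    if out_path is not None:
        counts.to_csv(out_path, sep="\t", index=False)
    return counts
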
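"""Synthetic inputs for every pipeline stage.

The generator emulates the study conditions rather than generic data:

* **Reads** — 125 bp single-end stranded reads over a 400 nt rRNA fragment
  carrying the SRL motif exactly once. Depurination is simulated as the
  A-to-T shift at the target adenine: a reverse transcriptase that meets
  the abasic site preferentially inserts an adenine in the nascent cDNA,
  which reads out as T on the rRNA sense strand. Sequencing errors are
  independent per base, uniform over the three alternatives.
* **Counts** — negative-binomial gene-by-sample matrices (BCV ~ 0.35,
  within the study's 0.3-0.4 range) over a 2x2 factorial design
  (Spiroplasma x wasp, four replicates per treatment) with planted gene
  classes: male-biased genes silenced under the male-killing symbiont,
  wasp-responsive genes, Spiroplasma-responsive genes, the restored
  Group A/B patterns, the S+wasp-specific Group C pattern, and the
  male-gonad ordering S-W- > S-wasp > S+W- = S+wasp.
* **Ct tables** — qPCR Ct values consistent with requested delta-Ct after
  efficiency correction, plus Gaussian replicate noise.

Every simulation emits a truth table sufficient to score recovery without
re-reading the config. Randomness comes from numpy's PCG64; per-replicate
sub-streams are seeded with SeedSequence((seed, stream_index)) so fixed
seeds give byte-identical output regardless of ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .depurination import SRLTarget, locate_srl
from .io_formats import ReadRecord, ReferenceRecord
from .qpcr import correct_ct, CtRecord

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_TREATMENTS = ("S-W-", "S+W-", "S-Lh", "S+Lh")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference fragment
# ---------------------------------------------------------------------------

def default_srl_reference(
    length: int = 400,
    motif_start: int = 180,
    seed: int = 20_240_428,
    target: SRLTarget = SRLTarget(),
) -> ReferenceRecord:
    """A synthetic 400 nt rRNA fragment embedding the SRL motif exactly once.

    The flanking sequence is synthetic (random, fixed by ``seed``) — only
    the 13-mer motif context is defined by the assay. Regenerates flanks
    until the motif occurs exactly once.
    """
    rng = np.random.default_rng(seed)
    motif = target.motif
    if not 0 <= motif_start <= length - len(motif):
        raise ValueError("motif does not fit in the requested fragment")
    for _ in range(100):
        flank_left = "".join(rng.choice(_BASES, size=motif_start))
        flank_right = "".join(rng.choice(_BASES, size=length - motif_start - len(motif)))
        seq = flank_left + motif + flank_right
        if seq.count(motif) == 1 and _revcomp(seq).count(motif) == 0:
            return ReferenceRecord(id="rRNA_28S_fragment", sequence=seq)
    raise RuntimeError("could not embed motif uniquely")  # pragma: no cover


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    """Parameters for simulated depurination read sets.

    depurination_rate: probability that a target-covering read carries the
        misincorporation signature (default 0.15, a clearly detectable but
        sub-saturating lesion load).
    error_rate: per-base sequencing error rate (default 1e-3, Illumina-like).
    strand_fraction_forward: fraction of reads emitted on the reference
        sense strand (0.5 unless the stranded protocol is being mimicked).
    non_t_fraction: fraction of depurination signatures that read out as C
        or G instead of T (0 by default; robustness testing only).
    """

    seed: int = 0
    reference: ReferenceRecord = field(default_factory=default_srl_reference)
    read_length: int = 125
    n_reads: int = 2000
    depurination_rate: float = 0.15
    error_rate: float = 1e-3
    strand_fraction_forward: float = 0.5
    non_t_fraction: float = 0.0
    target: SRLTarget = field(default_factory=SRLTarget)

    def __post_init__(self) -> None:
        if not 0 <= self.depurination_rate <= 1:
            raise ValueError("depurination_rate must be in [0,1]")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if not 0 <= self.strand_fraction_forward <= 1:
            raise ValueError("strand_fraction_forward must be in [0,1]")
        if not 0 <= self.non_t_fraction <= 1:
            raise ValueError("non_t_fraction must be in [0,1]")
        if self.read_length > len(self.reference):
            raise ValueError("read_length exceeds reference length")
        if self.reference.sequence.count(self.target.motif) != 1:
            raise ValueError("reference must contain the motif exactly once")


def simulate_reads(
    config: ReadSimConfig, replicate_id: str = "rep1", stream: int = 0
) -> tuple[list[ReadRecord], dict]:
    """One replicate of depurinated stranded reads plus its truth record.

    Reads start uniformly along the fragment. A read covering the target
    adenine carries the depurination signature with probability d (T, or
    C/G for the configured non-T fraction); per-base errors at rate
    ``error_rate`` are applied afterwards, uniform over the three
    alternatives, sparing the target position of depurinated reads (the
    signature is a deterministic consequence of the abasic site, not a
    sequencing error). Reverse-orientation reads are reverse-complemented
    with the orientation recorded.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, stream)))
    ref = config.reference.sequence
    span = locate_srl(config.reference, config.target)
    n, L = config.n_reads, config.read_length
    max_start = len(ref) - L
    ref_codes = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)

    starts = rng.integers(0, max_start + 1, size=n)
    seqs = ref_codes[starts[:, None] + np.arange(L)[None, :]].copy()
    target_local = span.target_position - starts
    covers = (starts <= span.target_position) & (target_local < L)
    depurinated = covers & (rng.random(n) < config.depurination_rate)
    dep_rows = np.nonzero(depurinated)[0]
    signature = np.full(dep_rows.size, ord("T"), dtype=np.uint8)
    if config.non_t_fraction:
        non_t = rng.random(dep_rows.size) < config.non_t_fraction
        signature[non_t] = np.where(
            rng.random(np.count_nonzero(non_t)) < 0.5, ord("C"), ord("G")
        )
    seqs[dep_rows, target_local[dep_rows]] = signature

    err = rng.random((n, L)) < config.error_rate
    err[dep_rows, target_local[dep_rows]] = False  # the signature is not an error
    err_rows, err_cols = np.nonzero(err)
    if err_rows.size:
        # substitute uniformly among the three alternative bases
        alt = np.zeros((256, 3), dtype=np.uint8)
        for base, others in {
            "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
        }.items():
            alt[ord(base)] = [ord(o) for o in others]
        choice = rng.integers(0, 3, size=err_rows.size)
        seqs[err_rows, err_cols] = alt[seqs[err_rows, err_cols], choice]

    forward = rng.random(n) < config.strand_fraction_forward
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip("ACGTN", "TGCAN"):
        comp[ord(a)] = ord(b)
    rev_rows = np.nonzero(~forward)[0]
    seqs[rev_rows] = comp[seqs[rev_rows][:, ::-1]]

    qualities = tuple([40] * L)
    reads = [
        ReadRecord(
            id=f"{replicate_id}:read{i}:{starts[i]}",
            sequence=seqs[i].tobytes().decode("ascii"),
            qualities=qualities,
            orientation="forward" if forward[i] else "reverse",
        )
        for i in range(n)
    ]
    truth = {
        "replicate_id": replicate_id,
        "depurination_rate": config.depurination_rate,
        "error_rate": config.error_rate,
        "n_reads": config.n_reads,
        "target_position": span.target_position,
    }
    return reads, truth


def simulate_read_treatments(
    config: ReadSimConfig,
    treatments: dict[str, float],
    replicates: int = 4,
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Read sets for a factorial design: one replicate per (treatment, rep),
    with the per-treatment depurination rate from ``treatments``."""
    from dataclasses import replace

    out: dict[str, list[ReadRecord]] = {}
    truth_rows = []
    stream = 0
    for treatment, rate in treatments.items():
        for rep in range(1, replicates + 1):
            stream += 1
            rep_id = f"{treatment}_{rep}"
            cfg = replace(config, depurination_rate=rate)
            reads, truth = simulate_reads(cfg, replicate_id=rep_id, stream=stream)
            out[rep_id] = reads
            truth_rows.append({**truth, "treatment": treatment})
    return out, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Parameters for the factorial negative-binomial count generator.

    Effect sizes are log2 fold-changes; ``planted_lfc`` (default 2, i.e.
    4-fold) drives the wasp/Spiroplasma/Group A/B/C plants —
    within the range the study had good power to detect at 4 replicates.
    ``male_silencing_factor`` multiplies male-biased baselines under
    Spiroplasma (near-zero: those transcripts come from males that the
    male-killing symbiont removed). Class sizes are gene counts; remaining
    genes are nulls.
    """

    seed: int = 0
    n_genes: int = 2000
    library_size: int = 200_000
    library_variation: float = 0.2  # uniform half-width of relative depth
    bcv: float = 0.35
    replicates: int = 4
    wasp: str = "lh"
    time: str = "T2"
    planted_lfc: float = 2.0
    male_silencing_factor: float = 0.02
    # male-gonad ordering multipliers (control, S+W-, S-wasp, S+wasp)
    gonad_profile: tuple = (1.0, 0.02, 0.4, 0.02)
    class_sizes: dict = field(default_factory=lambda: {
        "male_biased": 150,
        "wasp_up": 60,
        "wasp_down": 60,
        "spiroplasma_down": 80,
        "group_A": 20,
        "group_B": 20,
        "group_C": 20,
        "male_gonad_pattern": 30,
    })

    def __post_init__(self) -> None:
        if self.bcv < 0:
            raise ValueError("bcv must be non-negative")
        if not 0 <= self.library_variation < 1:
            raise ValueError("library_variation must be in [0, 1)")
        if sum(self.class_sizes.values()) > self.n_genes:
            raise ValueError("planted class sizes exceed n_genes")


def make_design(
    wasp: str = "lh", time: str = "T2", replicates: int = 4
) -> pd.DataFrame:
    """The four-treatment factorial design table (one wasp, one time point)."""
    rows = []
    for spiro, wsp in (
        ("absent", "none"), ("present", "none"), ("absent", wasp), ("present", wasp)
    ):
        for rep in range(1, replicates + 1):
            s = "S+" if spiro == "present" else "S-"
            w = "W-" if wsp == "none" else wsp.capitalize()
            rows.append({
                "sample_id": f"{s}{w}_{rep}_{time}",
                "spiroplasma": spiro,
                "wasp": wsp,
                "time": time,
                "replicate": rep,
            })
    return pd.DataFrame(rows)


def _treatment_multipliers(cls: str, cfg: CountSimConfig) -> np.ndarray:
    """Per-treatment mean multipliers, order (control, S+W-, S-wasp, S+wasp)."""
    e = 2.0 ** cfg.planted_lfc
    m = cfg.male_silencing_factor
    profiles = {
        "null": (1, 1, 1, 1),
        "male_biased": (1, m, 1, m),
        "wasp_up": (1, 1, e, e),
        "wasp_down": (1, 1, 1 / e, 1 / e),
        "spiroplasma_down": (1, 1 / e, 1, 1 / e),
        "group_A": (1, 1, e, 1),        # wasp raises, Spiroplasma restores
        "group_B": (1, 1, 1 / e, 1),    # wasp lowers, Spiroplasma restores
        "group_C": (1, 1, 1, e),        # boosted only under S+wasp
        "male_gonad_pattern": cfg.gonad_profile,
    }
    return np.asarray(profiles[cls], dtype=float)


def _true_contrast_lfc(mult: np.ndarray) -> dict:
    with np.errstate(divide="ignore"):
        return {
            "true_lfc_blue": float(np.log2(mult[1] / mult[0])),
            "true_lfc_red": float(np.log2(mult[2] / mult[0])),
            "true_lfc_green": float(np.log2(mult[3] / mult[2])),
        }


def simulate_counts(
    config: CountSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Factorial NB count matrix with planted gene classes.

    Returns (counts genes x samples, design table, truth table). Counts are
    gamma-Poisson draws with mean = baseline x treatment multiplier x
    relative library size and variance mu + bcv^2 mu^2. Planted baselines
    are kept comfortably above the CPM filter so that class recovery
    measures the classifier, not the expression floor.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1_000)))
    design = make_design(config.wasp, config.time, config.replicates)
    treatments = design.apply(
        lambda r: ("S+" if r.spiroplasma == "present" else "S-")
        + ("W-" if r.wasp == "none" else "wasp"),
        axis=1,
    ).to_numpy()
    t_index = {"S-W-": 0, "S+W-": 1, "S-wasp": 2, "S+wasp": 3}
    col_t = np.array([t_index[t] for t in treatments])

    classes = []
    for cls, size in config.class_sizes.items():
        classes.extend([cls] * size)
    classes.extend(["null"] * (config.n_genes - len(classes)))
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    # baseline relative expression: broad lognormal for nulls, moderate-to-high
    # uniform (log2 32..512 expected counts) for planted classes
    mean_count = config.library_size / config.n_genes
    baselines = np.empty(config.n_genes)
    for i, cls in enumerate(classes):
        if cls == "null":
            baselines[i] = float(rng.lognormal(mean=0.0, sigma=1.2)) * mean_count
        else:
            baselines[i] = float(2.0 ** rng.uniform(5, 9))
    lv = config.library_variation
    lib_rel = rng.uniform(1.0 - lv, 1.0 + lv, size=len(design))

    mu = np.empty((config.n_genes, len(design)))
    for i, cls in enumerate(classes):
        mult = _treatment_multipliers(cls, config)
        mu[i, :] = baselines[i] * mult[col_t] * lib_rel
    phi = config.bcv ** 2
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design.sample_id)
    truth_rows = []
    for gid, cls in zip(gene_ids, classes):
        mult = _treatment_multipliers(cls, config)
        truth_rows.append({"gene_id": gid, "class": cls, **_true_contrast_lfc(mult)})
    truth = pd.DataFrame(truth_rows)
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# Ct simulation
# ---------------------------------------------------------------------------

DEFAULT_EFFICIENCIES = {"RIP1": 0.995, "RIP2": 1.0, "RIP3_5": 1.0, "rpoB": 1.0}


def simulate_ct(
    deltas: dict[str, dict[str, float]],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    efficiencies: Optional[dict[str, float]] = None,
    reference_gene: str = "rpoB",
    reference_corrected_ct: float = 25.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct tables consistent with requested delta-Ct values.

    ``deltas`` maps design-cell label -> {gene: requested delta Ct}. Raw Ct
    values are back-computed through the efficiency correction so that
    noise-free tables round-trip exactly; Gaussian noise (sd ``noise_sd``)
    is added to each target's corrected Ct per replicate.
    Returns (ct table, truth table).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    eff = dict(DEFAULT_EFFICIENCIES)
    if efficiencies:
        eff.update(efficiencies)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2_000)))
    rows = []
    truth_rows = []

    def raw_ct(gene: str, corrected: float) -> float:
        slope = np.log2(1.0 + eff[gene])
        return corrected / slope

    for cell, gene_deltas in deltas.items():
        for rep in range(1, replicates + 1):
            sample_id = f"{cell}_{rep}"
            rows.append({
                "sample_id": sample_id, "gene": reference_gene,
                "ct": raw_ct(reference_gene, reference_corrected_ct),
                "efficiency": eff[reference_gene],
            })
            for gene, delta in gene_deltas.items():
                corrected = reference_corrected_ct - delta
                corrected += float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
                rows.append({
                    "sample_id": sample_id, "gene": gene,
                    "ct": raw_ct(gene, corrected),
                    "efficiency": eff[gene],
                })
                truth_rows.append({
                    "sample_id": sample_id, "gene": gene, "true_delta": delta,
                })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
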
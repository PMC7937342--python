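"""Depurination detection at the sarcin-ricin loop (SRL) target adenine.

Ribosome-inactivating proteins (RIPs) remove a specific adenine from the
universally conserved SRL of the 28S rRNA, leaving an abasic site. In
cDNA-based sequencing data the lesion shows up as an A-to-T shift at that
position, because reverse transcriptase preferentially inserts an adenine
opposite the abasic site. This module quantifies that shift from reads or
alignments against an rRNA reference:

1. locate the conserved 13-mer motif (default TACGAGAGGAACC, target adenine
   at offset 4) in the reference;
2. retain only reads whose alignment fully covers the motif, dropping reads
   above a mismatch cap (the target column itself is exempt — the signal
   being measured must not count against retention);
3. tally A/C/G/T/other at the target column, excluding reads gapped there;
4. estimate the adenine fraction with a Wilson 95% interval and flag
   replicates with fewer retained reads than the QC minimum;
5. compare groups with a ridge-penalized binomial GLM whose deviance
   chi-square stays finite under complete separation (all-zero non-A
   groups), with an exact Fisher test on pooled counts as a secondary check.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io_formats import (
    AlignmentRecord,
    ConfigurationError,
    ReadRecord,
    ReferenceRecord,
    RunConfig,
    write_tsv,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MotifError(ValueError):
    """SRL motif absent from, or ambiguous in, the reference."""


@dataclass(frozen=True)
class SRLTarget:
    """The conserved SRL motif and the offset of the RIP-target adenine."""

    motif: str = "TACGAGAGGAACC"
    target_offset: int = 4

    def __post_init__(self) -> None:
        if len(self.motif) < 5:
            raise ValueError("motif too short to anchor the target site")
        if not 0 <= self.target_offset < len(self.motif):
            raise ValueError("target_offset outside motif")
        if self.motif[self.target_offset] != "A":
            raise ValueError(
                f"motif position {self.target_offset} is "
                f"{self.motif[self.target_offset]!r}, expected the target adenine"
            )


@dataclass(frozen=True)
class SRLSpan:
    """Location of the motif on a reference (0-based, half-open)."""

    reference_id: str
    start: int
    end: int
    target_position: int


@dataclass
class SiteBaseCounts:
    """Per-sample tally of read bases at the target position."""

    sample_id: str
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    other: int = 0
    gapped: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "c", "g", "t", "other", "gapped"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    @property
    def total_ungapped(self) -> int:
        return self.a + self.c + self.g + self.t + self.other


@dataclass
class DepurinationEstimate:
    sample_id: str
    n_reads: int
    adenine_fraction: float
    depurination_fraction: float
    t_fraction: float
    ci_low: float
    ci_high: float
    passed_qc: bool


@dataclass
class DepurinationTestResult:
    chi_sq: float
    df: int
    p_value: float
    group_effect: float
    group_effect_se: float
    model: str
    fisher_p: Optional[float] = None
    groups: tuple = ()


# ---------------------------------------------------------------------------
# Motif location
# ---------------------------------------------------------------------------

def locate_srl(reference: ReferenceRecord, target: SRLTarget = SRLTarget()) -> SRLSpan:
    """Find the unique exact occurrence of the motif in the reference.

    Returns the motif span (0-based half-open) and the absolute coordinate
    of the target adenine. Zero hits raise MotifError ("motif absent");
    multiple hits raise MotifError (coordinates must then be supplied).
    """
    hits = [m.start() for m in re.finditer(re.escape(target.motif), reference.sequence)]
    if not hits:
        raise MotifError(f"motif {target.motif!r} absent from reference {reference.id!r}")
    if len(hits) > 1:
        raise MotifError(
            f"motif {target.motif!r} occurs {len(hits)} times in {reference.id!r} "
            "at " + ", ".join(str(h) for h in hits) + "; supply coordinates explicitly"
        )
    start = hits[0]
    return SRLSpan(
        reference_id=reference.id,
        start=start,
        end=start + len(target.motif),
        target_position=start + target.target_offset,
    )


# ---------------------------------------------------------------------------
# Read retention and base calling
# ---------------------------------------------------------------------------

@dataclass
class AssignResult:
    """Base calls at the target plus a full accounting of dropped reads."""

    calls: list  # elements of {"A","C","G","T","other","gap"}
    dropped: dict = field(default_factory=dict)

    def total_input(self) -> int:
        return len(self.calls) + sum(self.dropped.values())


def _call_from_base(base: str) -> str:
    base = base.upper()
    return base if base in "ACGT" else "other"


def assign_reads(
    source: Sequence,
    reference: ReferenceRecord,
    span: SRLSpan,
    config: RunConfig = RunConfig(),
) -> AssignResult:
    """Retain reads that fully cover the motif span and call the target base.

    Alignment mode (AlignmentRecord input): a read is retained iff its
    alignment covers every reference column in [span.start, span.end).
    Reads whose mismatch fraction (substitutions over aligned columns,
    target column exempt) exceeds ``config.max_mismatch_fraction`` are
    dropped. A read-side gap at the target column yields a "gap" call,
    which downstream counting excludes from base tallies.

    Raw-read mode (ReadRecord input): anchoring is by exact match of the
    motif with the target position wildcarded, in the read or its reverse
    complement; a match implies full motif coverage and exact flanks.

    All drops are tallied by reason; nothing is silently discarded.
    """
    calls: list[str] = []
    dropped = {"partial_coverage": 0, "high_mismatch": 0, "no_anchor": 0,
               "ambiguous_anchor": 0}
    items = list(source)
    if items and isinstance(items[0], AlignmentRecord):
        for aln in items:
            call = _call_from_alignment(aln, reference, span, config)
            if call in dropped:
                dropped[call] += 1
            else:
                calls.append(call)
    else:
        pattern = _wildcard_pattern(reference, span)
        for read in items:
            call = _call_from_raw_read(read, pattern, span)
            if call in dropped:
                dropped[call] += 1
            else:
                calls.append(call)
    return AssignResult(calls=calls, dropped={k: v for k, v in dropped.items() if v})


def _call_from_alignment(
    aln: AlignmentRecord,
    reference: ReferenceRecord,
    span: SRLSpan,
    config: RunConfig,
) -> str:
    ref_to_read: dict[int, Optional[int]] = {}
    aligned_cols = 0
    mismatches = 0
    for read_pos, ref_pos in aln.aligned_pairs:
        if ref_pos is not None:
            ref_to_read[ref_pos] = read_pos
        if read_pos is not None and ref_pos is not None:
            aligned_cols += 1
            if (
                aln.sequence is not None
                and ref_pos != span.target_position
                and aln.sequence[read_pos].upper() != reference.sequence[ref_pos]
            ):
                mismatches += 1
    covered = all(pos in ref_to_read for pos in range(span.start, span.end))
    if not covered:
        return "partial_coverage"
    if aln.sequence is not None:
        edit = mismatches / aligned_cols if aligned_cols else 0.0
    else:  # no sequence available: fall back to the aligner-reported fraction
        edit = aln.edit_fraction if aln.edit_fraction is not None else 0.0
    if edit > config.max_mismatch_fraction:
        return "high_mismatch"
    read_pos = ref_to_read[span.target_position]
    if read_pos is None:
        return "gap"
    if aln.sequence is None:
        raise ConfigurationError(
            f"alignment {aln.read_id!r} carries no sequence; cannot call target base"
        )
    return _call_from_base(aln.sequence[read_pos])


def _wildcard_pattern(reference: ReferenceRecord, span: SRLSpan) -> re.Pattern:
    motif = reference.sequence[span.start:span.end]
    offset = span.target_position - span.start
    return re.compile(
        re.escape(motif[:offset]) + "([ACGTN])" + re.escape(motif[offset + 1:])
    )


def _call_from_raw_read(read: ReadRecord, pattern: re.Pattern, span: SRLSpan) -> str:
    for seq in (read.sequence.upper(), reverse_complement(read.sequence.upper())):
        hits = list(pattern.finditer(seq))
        if len(hits) == 1:
            return _call_from_base(hits[0].group(1))
        if len(hits) > 1:
            return "ambiguous_anchor"
    return "no_anchor"


def count_bases(calls: Iterable[str], sample_id: str) -> SiteBaseCounts:
    """Exhaustive, mutually exclusive tally of target-site calls.

    Gap calls go to ``gapped`` only and never contribute to base counts;
    'N' and other ambiguity codes count as ``other``.
    """
    counts = SiteBaseCounts(sample_id=sample_id)
    for call in calls:
        if call == "gap":
            counts.gapped += 1
        elif call == "A":
            counts.a += 1
        elif call == "C":
            counts.c += 1
        elif call == "G":
            counts.g += 1
        elif call == "T":
            counts.t += 1
        else:
            counts.other += 1
    return counts


def brute_force_count(
    reads: Sequence[ReadRecord],
    reference: ReferenceRecord,
    target: SRLTarget,
    sample_id: str = "brute",
) -> SiteBaseCounts:
    """Independent pure-string oracle: slide the wildcarded motif over each
    read and its reverse complement and tally the base at the wildcard.

    Deliberately avoids the assign_reads machinery; used only in tests.
    """
    span = locate_srl(reference, target)
    motif = target.motif
    off = target.target_offset
    counts = SiteBaseCounts(sample_id=sample_id)
    for read in reads:
        found = None
        for seq in (read.sequence.upper(), reverse_complement(read.sequence.upper())):
            matches = []
            for i in range(len(seq) - len(motif) + 1):
                window = seq[i:i + len(motif)]
                if window[:off] == motif[:off] and window[off + 1:] == motif[off + 1:]:
                    matches.append(window[off])
            if len(matches) == 1:
                found = matches[0]
                break
            if len(matches) > 1:
                found = "ambiguous"
                break
        if found is None or found == "ambiguous":
            continue
        if found == "A":
            counts.a += 1
        elif found == "C":
            counts.c += 1
        elif found == "G":
            counts.g += 1
        elif found == "T":
            counts.t += 1
        else:
            counts.other += 1
    return counts


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def estimate_depurination(
    counts: SiteBaseCounts, config: RunConfig = RunConfig()
) -> DepurinationEstimate:
    """Adenine fraction with a Wilson 95% score interval and QC flag.

    The Wilson interval behaves at the 0/1 boundaries where the Wald
    interval collapses — relevant here because uninfected samples sit at
    adenine fraction ~1. Zero retained reads yield NaN fractions and a
    failed QC flag rather than an error.
    """
    n = counts.total_ungapped
    if n == 0:
        return DepurinationEstimate(
            sample_id=counts.sample_id, n_reads=0,
            adenine_fraction=float("nan"), depurination_fraction=float("nan"),
            t_fraction=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            passed_qc=False,
        )
    a_frac = counts.a / n
    lo, hi = proportion_confint(counts.a, n, alpha=0.05, method="wilson")
    # guard float jitter at the 0/1 boundaries so the interval brackets p-hat
    lo = min(max(float(lo), 0.0), a_frac)
    hi = max(min(float(hi), 1.0), a_frac)
    return DepurinationEstimate(
        sample_id=counts.sample_id,
        n_reads=n,
        adenine_fraction=a_frac,
        depurination_fraction=1.0 - a_frac,
        t_fraction=counts.t / n,
        ci_low=float(lo),
        ci_high=float(hi),
        passed_qc=n >= config.min_reads_per_replicate,
    )


# ---------------------------------------------------------------------------
# Penalized binomial GLM group comparison
# ---------------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    # y: successes (non-A), n: trials, mu: fitted probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n * (1 - mu))), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _penalized_binomial_irls(
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    prior_scale: float,
    intercept_scale: float = 10.0,
    max_iter: int = 200,
    tol: float = 1e-10,
):
    """Binomial IRLS with an independent Gaussian (ridge) penalty per
    coefficient: prior sd ``intercept_scale`` on the intercept and
    ``prior_scale`` on the remaining (dummy-coded) coefficients.

    The penalty keeps estimates finite under complete separation (groups
    with zero non-A reads); it washes out as counts grow, so the deviance
    chi-square converges to the unpenalized likelihood-ratio statistic.
    """
    p = X.shape[1]
    penalties = np.full(p, 1.0 / prior_scale**2)
    penalties[0] = 1.0 / intercept_scale**2
    Lambda = np.diag(penalties)
    beta = np.zeros(p)
    # start the intercept at the pooled empirical logit
    pooled = (y.sum() + 0.5) / (n.sum() + 1.0)
    beta[0] = math.log(pooled / (1 - pooled))
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = n * mu * (1 - mu)
        z = eta + (y - n * mu) / w
        XtW = X.T * w
        H = XtW @ X + Lambda
        beta_new = np.linalg.solve(H, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = n * mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X + Lambda)
    deviance = _binomial_deviance(y, n, mu)
    return beta, cov, deviance


def compare_depurination(
    samples: Sequence[SiteBaseCounts],
    groups: Sequence[str],
    config: RunConfig = RunConfig(),
) -> DepurinationTestResult:
    """Test for a group difference in the non-adenine (depurination) rate.

    Fits a binomial regression of (non-A, A) per replicate on group with a
    Gaussian penalty (sd ``config.prior_scale`` on group coefficients), and
    reports the difference in unpenalized binomial deviance between the
    intercept-only and group models as a chi-square with df = groups - 1.
    Replicates failing the read-count QC are excluded. For two groups an
    exact two-sided Fisher test on pooled counts is reported alongside.
    """
    if len(samples) != len(groups):
        raise ValueError("samples and groups must align")
    kept = [
        (s, g)
        for s, g in zip(samples, groups)
        if s.total_ungapped >= config.min_reads_per_replicate
    ]
    labels = sorted({g for _, g in kept})
    if len(labels) < 2:
        raise ValueError(
            f"need >=2 groups with QC-passing replicates, have {labels}"
        )
    n = np.array([s.total_ungapped for s, _ in kept], dtype=float)
    y = np.array([s.total_ungapped - s.a for s, _ in kept], dtype=float)  # non-A
    k = len(labels)
    X_null = np.ones((len(kept), 1))
    X_full = np.ones((len(kept), k))
    for j, lab in enumerate(labels[1:], start=1):
        X_full[:, j] = [1.0 if g == lab else 0.0 for _, g in kept]
    _, _, dev_null = _penalized_binomial_irls(X_null, y, n, config.prior_scale)
    beta, cov, dev_full = _penalized_binomial_irls(X_full, y, n, config.prior_scale)
    chi_sq = max(0.0, dev_null - dev_full)
    df = k - 1
    p_value = float(stats.chi2.sf(chi_sq, df))
    p_value = min(max(p_value, np.nextafter(0, 1)), 1.0)

    fisher_p = None
    if k == 2:
        table = np.zeros((2, 2))
        for s, g in kept:
            i = labels.index(g)
            table[i, 0] += s.total_ungapped - s.a
            table[i, 1] += s.a
        fisher_p = float(stats.fisher_exact(table)[1])

    return DepurinationTestResult(
        chi_sq=chi_sq,
        df=df,
        p_value=p_value,
        group_effect=float(beta[1]),
        group_effect_se=float(math.sqrt(cov[1, 1])),
        model=f"binomial ridge (gaussian prior sd={config.prior_scale})",
        fisher_p=fisher_p,
        groups=tuple(labels),
    )


def unpenalized_lrt(
    samples: Sequence[SiteBaseCounts],
    groups: Sequence[str],
    config: RunConfig = RunConfig(),
) -> DepurinationTestResult:
    """Plain binomial likelihood-ratio test (no penalty), for comparison.

    The closed-form MLE per group is the pooled non-A proportion, so no
    iterative fit is needed; infinite estimates under separation are
    reflected only through zero cells in the deviance, which stays finite.
    """
    kept = [
        (s, g)
        for s, g in zip(samples, groups)
        if s.total_ungapped >= config.min_reads_per_replicate
    ]
    labels = sorted({g for _, g in kept})
    if len(labels) < 2:
        raise ValueError("need >=2 groups with QC-passing replicates")
    n = np.array([s.total_ungapped for s, _ in kept], dtype=float)
    y = np.array([s.total_ungapped - s.a for s, _ in kept], dtype=float)
    g_idx = np.array([labels.index(g) for _, g in kept])
    mu_null = np.full_like(n, np.clip(y.sum() / n.sum(), 1e-12, 1 - 1e-12))
    mu_full = np.empty_like(n)
    for i in range(len(labels)):
        sel = g_idx == i
        mu_full[sel] = np.clip(y[sel].sum() / n[sel].sum(), 1e-12, 1 - 1e-12)
    chi_sq = max(0.0, _binomial_deviance(y, n, mu_null) - _binomial_deviance(y, n, mu_full))
    df = len(labels) - 1
    return DepurinationTestResult(
        chi_sq=chi_sq, df=df,
        p_value=float(min(max(stats.chi2.sf(chi_sq, df), np.nextafter(0, 1)), 1.0)),
        group_effect=float("nan"), group_effect_se=float("nan"),
        model="binomial LRT (unpenalized)", groups=tuple(labels),
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def depurination_report(
    estimates: Sequence[DepurinationEstimate],
    counts: Sequence[SiteBaseCounts],
    tests: dict[str, DepurinationTestResult],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write ``<prefix>.counts.tsv`` (one row per sample) and
    ``<prefix>.summary.json`` (one block per contrast)."""
    out_prefix = Path(out_prefix)
    by_id = {c.sample_id: c for c in counts}
    rows = []
    for est in estimates:
        c = by_id.get(est.sample_id, SiteBaseCounts(sample_id=est.sample_id))
        rows.append({
            "sample_id": est.sample_id,
            "a": c.a, "c": c.c, "g": c.g, "t": c.t,
            "other": c.other, "gapped": c.gapped,
            "n_reads": est.n_reads,
            "adenine_fraction": est.adenine_fraction,
            "depurination_fraction": est.depurination_fraction,
            "t_fraction": est.t_fraction,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "passed_qc": est.passed_qc,
        })
    counts_path = out_prefix.with_suffix(out_prefix.suffix + ".counts.tsv") \
        if out_prefix.suffix else Path(str(out_prefix) + ".counts.tsv")
    write_tsv(pd.DataFrame(rows), counts_path)
    summary = {
        name: {
            "chi_sq": t.chi_sq, "df": t.df, "p_value": t.p_value,
            "group_effect": t.group_effect, "group_effect_se": t.group_effect_se,
            "model": t.model, "fisher_p": t.fisher_p, "groups": list(t.groups),
        }
        for name, t in tests.items()
    }
    json_path = Path(str(out_prefix) + ".summary.json")
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return counts_path, json_path


def read_report_counts(path: str | Path) -> list[DepurinationEstimate]:
    """Parse a ``.counts.tsv`` report back into estimates (round-trip)."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        DepurinationEstimate(
            sample_id=str(r.sample_id), n_reads=int(r.n_reads),
            adenine_fraction=float(r.adenine_fraction),
            depurination_fraction=float(r.depurination_fraction),
            t_fraction=float(r.t_fraction),
            ci_low=float(r.ci_low), ci_high=float(r.ci_high),
            passed_qc=bool(r.passed_qc),
        )
        for r in frame.itertuples()
    ]
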
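"""Evaluation quantities: per-base error rates, molecular recovery, VAF concordance.

Error rates count non-reference substitution bases (indels excluded, known-SNP
positions masked) over total considered bases, at three processing levels:
raw reads, consensus sequences, and the final call set of mutation-free
samples.  Molecular recovery relates the median consensus coverage over the
panel to the number of single-stranded molecules implied by the DNA input
mass (3.3 pg per haploid genome, two strands per genome equivalent).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import spearmanr

from .consensus import BASES, SSCSPileup, SSCSRecord, ref_base
from .regions import Panel, PositionMask
from .tagio import TaggedRead, parse_cigar

PG_PER_HAPLOID_GENOME = 0.0033  # ng
STRANDS_PER_GENOME_EQUIVALENT = 2


@dataclass
class ErrorRateReport:
    level: str  # raw | sscs | called
    errors: int
    bases: int

    @property
    def rate(self) -> float:
        return self.errors / self.bases if self.bases else 0.0

    def to_json(self) -> str:
        d = asdict(self)
        d["rate"] = self.rate
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ErrorRateReport":
        d = json.loads(s)
        return cls(level=d["level"], errors=d["errors"], bases=d["bases"])


class _PanelIndex:
    """Per-chrom sorted panel positions + reference bytes, for vectorized counting."""

    def __init__(self, panel: Panel, reference, snp_mask):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        sites: dict[str, list[int]] = {}
        for chrom, pos in panel.positions():
            if snp_mask is not None and (chrom, pos) in snp_mask:
                continue
            sites.setdefault(chrom, []).append(pos)
        for chrom, poss in sites.items():
            arr = np.asarray(sorted(set(poss)), dtype=np.int64)
            refb = np.asarray(
                [ord(ref_base(reference, chrom, int(p))) for p in arr], dtype=np.uint8
            )
            self.by_chrom[chrom] = (arr, refb)

    def count(self, chrom: str, start: int, bases: str) -> tuple[int, int]:
        """(substitution errors, considered bases) for a gapless aligned string."""
        if chrom not in self.by_chrom:
            return 0, 0
        ppos, refb = self.by_chrom[chrom]
        q = np.frombuffer(bases.encode(), dtype=np.uint8)
        pos = np.arange(start, start + q.size, dtype=np.int64)
        idx = np.searchsorted(ppos, pos)
        ok = (idx < ppos.size) & (ppos[np.minimum(idx, ppos.size - 1)] == pos)
        acgt = (q == ord("A")) | (q == ord("C")) | (q == ord("G")) | (q == ord("T"))
        ok &= acgt
        if not ok.any():
            return 0, 0
        mism = q[ok] != refb[idx[ok]]
        return int(mism.sum()), int(ok.sum())


def _aligned_mismatches(
    rec: TaggedRead | SSCSRecord,
    reference: Mapping[str, str],
    panel: Panel,
    snp_mask: Optional[PositionMask],
) -> tuple[int, int]:
    """(substitution errors, bases considered) for one read or consensus."""
    if isinstance(rec, SSCSRecord):
        chrom = rec.key.chrom
        pairs = (
            (rec.start + i, b) for i, b in enumerate(rec.bases) if b != "N"
        )
    else:
        chrom = rec.chrom
        out = []
        rpos, qpos = rec.start, 0
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                out.extend((rpos + i, rec.bases[qpos + i]) for i in range(n))
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            elif op in "IS":
                qpos += n
            elif op == "N":
                rpos += n
        pairs = iter(out)
    errors = bases = 0
    for pos, b in pairs:
        if not panel.contains(chrom, pos):
            continue
        if snp_mask is not None and (chrom, pos) in snp_mask:
            continue
        if b not in BASES:
            continue
        bases += 1
        if b != ref_base(reference, chrom, pos):
            errors += 1
    return errors, bases


def error_rate_raw(
    reads: Iterable[TaggedRead],
    reference: Mapping[str, str],
    panel: Panel,
    snp_mask: Optional[PositionMask] = None,
) -> ErrorRateReport:
    """Substitution error rate of raw aligned reads over the panel."""
    _require_panel(panel)
    index = _PanelIndex(panel, reference, snp_mask)
    errors = bases = 0
    for r in reads:
        ops = {op for op, _ in parse_cigar(r.cigar)}
        if ops == {"M"}:
            e, b = index.count(r.chrom, r.start, r.bases)
        else:
            e, b = _aligned_mismatches(r, reference, panel, snp_mask)
        errors += e
        bases += b
    return ErrorRateReport("raw", errors, bases)


def error_rate_sscs(
    sscs: Iterable[SSCSRecord],
    reference: Mapping[str, str],
    panel: Panel,
    snp_mask: Optional[PositionMask] = None,
) -> ErrorRateReport:
    """Substitution error rate at consensus level (N bases excluded)."""
    _require_panel(panel)
    index = _PanelIndex(panel, reference, snp_mask)
    errors = bases = 0
    for rec in sscs:
        e, b = index.count(rec.key.chrom, rec.start, rec.bases)
        errors += e
        bases += b
    return ErrorRateReport("sscs", errors, bases)


def error_rate_called(
    pass_alt_counts: Iterable[int],
    panel: Panel,
    n_samples: int,
    snp_mask: Optional[PositionMask] = None,
) -> ErrorRateReport:
    """Final-pipeline error rate from PASS calls in mutation-free samples.

    errors = total alt consensus molecules across false PASS calls; bases =
    (unmasked panel positions) × n_samples, the per-base false-call rate
    interpretation of errors per base considered.
    """
    _require_panel(panel)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n_pos = sum(
        1
        for c, p in panel.positions()
        if snp_mask is None or (c, p) not in snp_mask
    )
    errors = sum(pass_alt_counts)
    return ErrorRateReport("called", errors, n_pos * n_samples)


def _require_panel(panel: Panel) -> None:
    if panel.n_positions() == 0:
        raise ValueError("empty panel")


@dataclass
class RecoveryReport:
    input_mass_ng: float
    genome_equivalents: float
    input_molecules: float
    recovered_molecules: float
    pg_per_haploid_genome: float = PG_PER_HAPLOID_GENOME * 1000
    strands_per_genome_equivalent: int = STRANDS_PER_GENOME_EQUIVALENT

    @property
    def recovery(self) -> float:
        return self.recovered_molecules / self.input_molecules

    def to_json(self) -> str:
        d = asdict(self)
        d["recovery"] = self.recovery
        return json.dumps(d)


def molecular_recovery(
    sscs_pileup: SSCSPileup, input_mass_ng: float
) -> RecoveryReport:
    """Fraction of input single strands recovered as consensus molecules.

    recovered = median consensus coverage over panel positions; input =
    2 × (mass / 3.3 pg) single strands.
    """
    if input_mass_ng <= 0:
        raise ValueError("input mass must be positive")
    covs = [sscs_pileup.coverage(c, p) for c, p in sscs_pileup.panel.positions()]
    recovered = float(np.median(covs)) if covs else 0.0
    ge = input_mass_ng / PG_PER_HAPLOID_GENOME
    return RecoveryReport(
        input_mass_ng=input_mass_ng,
        genome_equivalents=ge,
        input_molecules=STRANDS_PER_GENOME_EQUIVALENT * ge,
        recovered_molecules=recovered,
    )


def vaf_concordance(pairs: list[tuple[float, float]]) -> dict:
    """Spearman rank correlation plus Bland–Altman agreement statistics.

    limits of agreement = bias ± 2 SD of the pairwise differences.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 VAF pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    rho, pval = spearmanr(a, b)
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "rank_correlation": float(rho),
        "p_value": float(pval),
        "bias": bias,
        "limits_of_agreement": [bias - 2 * sd, bias + 2 * sd],
        "n": len(pairs),
    }
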
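"""De novo variant calling against the background error profile.

Every non-SNP panel position with sufficient consensus coverage contributes
hypotheses — one per alternative allele — whether or not any alt molecule was
observed.  Observed candidates are scored with a one-sided binomial survival
test against the profile's conservative upper-bound error rate, p-values are
Bonferroni-adjusted over the full hypothesis universe m (so the global
probability of declaring a mutation-free sample mutated stays below alpha),
and surviving candidates pass through the filter chain: minimum consensus
coverage, support on both strands, limited strand bias (exact 2×2 test), and
a minimum indel length.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

from scipy.stats import binom, fisher_exact

from .consensus import BASES, SSCSPileup
from .errormodel import ErrorProfile, massart_upper_bound
from .regions import PositionMask

FILTER_LABELS = (
    "single_strand",
    "strand_bias",
    "low_coverage",
    "indel_too_short",
    "snp_masked",
)


@dataclass(frozen=True)
class CallerConfig:
    alpha: float = 0.05
    min_sscs_coverage: int = 100
    require_both_strands: bool = True
    strand_bias_p_floor: float = 0.001
    min_indel_length: int = 3
    snp_mask: Optional[PositionMask] = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_sscs_coverage < 1:
            raise ValueError("min_sscs_coverage must be >= 1")
        if self.min_indel_length < 1:
            raise ValueError("min_indel_length must be >= 1")


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str  # base, or "del:<len>" / "ins:<seq>"
    alt_f: int
    alt_r: int
    coverage: int
    vaf: float
    p_raw: float
    p_adj: float
    filters: set[str] = dc_field(default_factory=set)

    @property
    def alt_total(self) -> int:
        return self.alt_f + self.alt_r

    @property
    def passed(self) -> bool:
        return not self.filters


@dataclass
class TestUniverse:
    """Size of the Bonferroni universe and bookkeeping counts."""

    m: int
    n_positions_tested: int = 0
    n_low_coverage: int = 0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")


def test_position(alt_count: int, coverage: int, epsilon_up: float) -> float:
    """Upper-tail binomial p-value P(X >= alt_count), X ~ Bin(coverage, ε_up)."""
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0 <= alt_count <= coverage):
        raise ValueError("need 0 <= alt_count <= coverage")
    if not (0 <= epsilon_up <= 1):
        raise ValueError("epsilon_up must be in [0, 1]")
    return float(binom.sf(alt_count - 1, coverage, epsilon_up))


def bonferroni_adjust(p_values: list[float], m: int) -> list[float]:
    """p_adj = min(1, m * p_raw), order-preserving."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, m * p) for p in p_values]


def strand_bias_test(alt_f: int, alt_r: int, cov_f: int, cov_r: int) -> float:
    """Two-sided exact test of alt proportion between strands.

    2×2 table: [[alt_f, cov_f − alt_f], [alt_r, cov_r − alt_r]].
    """
    if min(alt_f, alt_r, cov_f - alt_f, cov_r - alt_r) < 0:
        raise ValueError("negative counts")
    if cov_f + cov_r < 1:
        raise ValueError("empty table")
    _, p = fisher_exact(
        [[alt_f, cov_f - alt_f], [alt_r, cov_r - alt_r]], alternative="two-sided"
    )
    return float(p)


def compute_vaf(alt_total: int, coverage: int) -> float:
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0 <= alt_total <= coverage):
        raise ValueError("need 0 <= alt_total <= coverage")
    return alt_total / coverage


def _indel_length(alt: str) -> int:
    kind, arg = alt.split(":", 1)
    return int(arg) if kind == "del" else len(arg)


def call_variants(
    sample: SSCSPileup,
    profile: ErrorProfile,
    cfg: CallerConfig = CallerConfig(),
) -> tuple[list[VariantCall], TestUniverse]:
    """Test a sample pileup against the error profile.

    Returns the emitted calls (candidates whose Bonferroni-adjusted p-value is
    below alpha, each carrying its set of failed filter labels; an empty set
    means PASS) and the test universe used for the correction.
    """
    if sample.panel.checksum() != profile.panel_checksum:
        raise ValueError("sample pileup and profile cover different panels")

    m = 0
    n_tested = 0
    n_low = 0
    candidates: list[tuple] = []  # (chrom,pos,ref,alt,alt_f,alt_r,cov,p_raw)

    for chrom, pos in sample.sites():
        if cfg.snp_mask is not None and (chrom, pos) in cfg.snp_mask:
            continue
        cov = sample.coverage(chrom, pos)
        if cov < cfg.min_sscs_coverage:
            n_low += 1
            continue
        ref = sample.ref[(chrom, pos)]
        n_tested += 1

        for alt in BASES:
            if alt == ref:
                continue
            entry = profile.lookup(chrom, pos, alt)
            if entry is None:
                continue
            m += 1
            f, r = sample.allele_counts(chrom, pos, alt)
            if f + r == 0:
                continue
            p_raw = test_position(f + r, cov, entry.epsilon_up)
            candidates.append((chrom, pos, ref, alt, f, r, cov, p_raw))

    # indel candidates: anchored events observed in the sample
    base_n: dict[tuple[str, int], int] = {}
    for e in profile.entries:
        if e.alt in BASES:
            base_n[(e.chrom, e.pos)] = e.n
    for (chrom, pos, desc), (f, r) in sorted(sample.indel_events.items()):
        if cfg.snp_mask is not None and (chrom, pos) in cfg.snp_mask:
            continue
        cov = sample.coverage(chrom, pos)
        if cov < cfg.min_sscs_coverage:
            continue
        if f + r == 0:
            continue
        entry = profile.lookup(chrom, pos, desc)
        if entry is not None:
            eps = entry.epsilon_up
        else:
            # unseen indel class at a profiled position: conservative zero-count
            # bound at the pooled control coverage
            n_bg = base_n.get((chrom, pos))
            if n_bg is None:
                continue
            eps = massart_upper_bound(0, n_bg, profile.delta, profile.method)
        m += 1
        ref = sample.ref[(chrom, pos)]
        p_raw = test_position(f + r, cov, eps)
        candidates.append((chrom, pos, ref, desc, f, r, cov, p_raw))

    universe = TestUniverse(m=m, n_positions_tested=n_tested, n_low_coverage=n_low)
    if not candidates:
        return [], universe

    p_adj = bonferroni_adjust([c[7] for c in candidates], max(m, 1))
    calls: list[VariantCall] = []
    for (chrom, pos, ref, alt, f, r, cov, p_raw), pa in zip(candidates, p_adj):
        if not (pa < cfg.alpha):  # strict: ties at alpha are not called
            continue
        filters: set[str] = set()
        if cfg.require_both_strands and (f == 0 or r == 0):
            filters.add("single_strand")
        cov_f, cov_r = sample.strand_coverage(chrom, pos)
        if strand_bias_test(f, r, cov_f, cov_r) < cfg.strand_bias_p_floor:
            filters.add("strand_bias")
        if ":" in alt and _indel_length(alt) < cfg.min_indel_length:
            filters.add("indel_too_short")
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                alt_f=f,
                alt_r=r,
                coverage=cov,
                vaf=compute_vaf(f + r, cov),
                p_raw=p_raw,
                p_adj=pa,
                filters=filters,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls, universe


# ---------------------------------------------------------------------------
# Output

_VCF_HEADER_LINES = [
    '##INFO=<ID=ALTF,Number=1,Type=Integer,Description="Alt consensus molecules, forward strand">',
    '##INFO=<ID=ALTR,Number=1,Type=Integer,Description="Alt consensus molecules, reverse strand">',
    '##INFO=<ID=COV,Number=1,Type=Integer,Description="Consensus coverage">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##INFO=<ID=PRAW,Number=1,Type=Float,Description="Raw binomial upper-tail p-value">',
    '##INFO=<ID=PADJ,Number=1,Type=Float,Description="Bonferroni-adjusted p-value">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Indel length (negative for deletions)">',
]


def write_vcf(
    calls: list[VariantCall],
    path: str,
    contig_lengths: Optional[dict[str, int]] = None,
    sample_name: str = "sample",
) -> None:
    """Emit calls as VCF v4.2 (1-based; indels as symbolic <DEL>/<INS> alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=sscall\n##sscall_sample={sample_name}\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        for lab in FILTER_LABELS:
            fh.write(f'##FILTER=<ID={lab},Description="{lab}">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if ":" in c.alt:
                kind, arg = c.alt.split(":", 1)
                length = int(arg) if kind == "del" else len(arg)
                alt_field = "<DEL>" if kind == "del" else "<INS>"
                svlen = f";SVLEN={-length if kind == 'del' else length}"
            else:
                alt_field = c.alt
                svlen = ""
            filt = ";".join(sorted(c.filters)) if c.filters else "PASS"
            info = (
                f"ALTF={c.alt_f};ALTR={c.alt_r};COV={c.coverage};"
                f"VAF={c.vaf:.6g};PRAW={c.p_raw:.6g};PADJ={c.p_adj:.6g}{svlen}"
            )
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{alt_field}\t.\t{filt}\t{info}\n"
            )


def write_calls_tsv(calls: list[VariantCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\talt_f\talt_r\tcoverage\tvaf\tp_raw\tp_adj\tfilters\n"
        )
        for c in calls:
            filt = ",".join(sorted(c.filters)) if c.filters else "PASS"
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.ref}\t{c.alt}\t{c.alt_f}\t{c.alt_r}\t"
                f"{c.coverage}\t{c.vaf:.6g}\t{c.p_raw:.6g}\t{c.p_adj:.6g}\t{filt}\n"
            )


def write_run_metadata(
    path: str,
    universe: TestUniverse,
    cfg: CallerConfig,
    profile: ErrorProfile,
    extra: Optional[dict] = None,
) -> None:
    meta = {
        "m": universe.m,
        "n_positions_tested": universe.n_positions_tested,
        "n_low_coverage": universe.n_low_coverage,
        "alpha": cfg.alpha,
        "min_sscs_coverage": cfg.min_sscs_coverage,
        "require_both_strands": cfg.require_both_strands,
        "strand_bias_p_floor": cfg.strand_bias_p_floor,
        "min_indel_length": cfg.min_indel_length,
        "profile_checksum": hashlib.sha256(
            profile.to_frame().to_csv(index=False).encode()
        ).hexdigest()[:16],
        "profile_delta": profile.delta,
        "profile_method": profile.method,
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
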
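"""Synthetic tagged-read simulator with a truth manifest.

Emulates the validation design of a tag-based cfDNA assay at desk scale:
~160 bp panel-restricted cfDNA fragments, each labelled with a random
molecular tag, amplified into a read family whose size follows a geometric
distribution, with independent per-base substitution/indel errors injected at
raw-read level, sequencing errors inside the tag itself, spike-in variants at
nominal VAFs, and cohorts of mutation-free "normal plasma" samples.

Two tiers are provided:

* :func:`simulate_sample` / :func:`simulate_cohort` — full read-level
  generation feeding the tagio → consensus pipeline, with a per-molecule
  truth manifest.
* :func:`simulate_sscs_pileup` — a consensus-level shortcut that draws an
  SSCS pileup directly at a stated coverage and per-molecule error rate, for
  experiments that exercise only the profile/caller stages at scale.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from .consensus import SSCSPileup
from .regions import Interval, Panel
from .tagio import AdapterSpec, RawRead, TaggedRead

# nominal spike-in dilution levels (fraction), mirroring a 5% / 1% / 0.5% /
# 0.1% / negative-control series
SPIKE_LEVELS = (0.05, 0.01, 0.005, 0.001, 0.0)

PG_PER_HAPLOID_GENOME = 0.0033  # ng
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpikeIn:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str  # single substituted base
    vaf: float


@dataclass
class SimulationConfig:
    """The stated world of one simulated sample.

    Defaults follow the assay's published operating point where one exists:
    22% molecular recovery, ~160 bp fragments (±20 bp uniform jitter), 10 nt
    tags.  Family size is geometric with mean 30, matching the assay's
    raw-to-consensus coverage ratio (~67,000x raw vs ~2,200x SSCS); the true
    distribution for this chemistry is not published.  Raw substitution rate
    1e-3 is a realistic semiconductor-sequencing figure.
    """

    seed: int = 0
    input_mass_ng: float = 20.0
    recovery: float = 0.22
    family_size_mean: float = 30.0
    raw_substitution_rate: float = 1e-3
    raw_indel_rate: float = 1e-4
    tag_error_rate: float = 1e-3
    tag_length: int = 10
    fragment_length: int = 160
    fragment_jitter: int = 20
    spike_ins: list[SpikeIn] = field(default_factory=list)
    n_molecules: Optional[int] = None  # overrides mass × recovery when set

    def __post_init__(self) -> None:
        for rate in (
            self.recovery,
            self.raw_substitution_rate,
            self.raw_indel_rate,
            self.tag_error_rate,
        ):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        for s in self.spike_ins:
            if not (0 <= s.vaf <= 1):
                raise ValueError("spike-in VAF must be in [0, 1]")

    def molecule_count(self) -> int:
        if self.n_molecules is not None:
            return self.n_molecules
        strands = 2 * self.input_mass_ng / PG_PER_HAPLOID_GENOME
        return int(round(strands * self.recovery))


@dataclass
class TruthManifest:
    """Ground truth for one simulated sample."""

    seed: int
    molecules: list[dict] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)  # nominal + realized VAF
    n_injected_errors: int = 0

    def family_size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for mol in self.molecules:
            hist[mol["n_reads"]] = hist.get(mol["n_reads"], 0) + 1
        return hist

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def load(cls, path: str) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# reference / panel fixtures

def make_reference(
    lengths: Mapping[str, int], seed: int = 0
) -> dict[str, str]:
    """A random reference over {A,C,G,T}, deterministic under the seed."""
    rng = np.random.default_rng(seed)
    return {
        chrom: rng.choice(_BASES, size=n).tobytes().decode()
        for chrom, n in lengths.items()
    }


def write_fasta(reference: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    import pyfaidx

    return {name: str(rec[:]) for name, rec in pyfaidx.Fasta(path).items()}


def default_panel(reference: Mapping[str, str], target_bp: int = 300) -> Panel:
    """One target interval per contig, centred, totalling ~target_bp."""
    per = max(1, target_bp // len(reference))
    ivs = []
    for chrom, seq in reference.items():
        mid = len(seq) // 2
        start = max(0, mid - per // 2)
        ivs.append(Interval(chrom, start, min(len(seq), start + per)))
    return Panel(ivs)


# ---------------------------------------------------------------------------
# read-level simulation

def _random_tag(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_bases(
    seq: np.ndarray, rng: np.random.Generator, rate: float
) -> tuple[np.ndarray, int]:
    """Substitute bases independently at ``rate``; returns (seq, n_changed)."""
    if rate <= 0:
        return seq, 0
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    if hit.size == 0:
        return seq, 0
    out = seq.copy()
    # shift by 1..3 positions in base alphabet: always a different base
    shifts = rng.integers(1, 4, size=hit.size)
    idx = np.searchsorted(_BASES, out[hit])
    out[hit] = _BASES[(idx + shifts) % 4]
    return out, int(hit.size)


def _inject_indel(
    seq: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """Inject one 1-3 bp deletion or insertion at a random interior position."""
    L = seq.size
    if L < 8:
        return seq, f"{L}M"
    length = int(rng.integers(1, 4))
    pos = int(rng.integers(1, L - length - 1))
    if rng.random() < 0.5:  # deletion
        out = np.concatenate([seq[:pos], seq[pos + length :]])
        cigar = f"{pos}M{length}D{L - pos - length}M"
    else:
        ins = rng.choice(_BASES, size=length)
        out = np.concatenate([seq[:pos], ins, seq[pos:]])
        cigar = f"{pos}M{length}I{L - pos}M"
    return out, cigar


def simulate_sample(
    cfg: SimulationConfig,
    panel: Panel,
    reference: Mapping[str, str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[TaggedRead], TruthManifest]:
    """Draw one sample: molecules, families, error-injected tagged reads.

    Deterministic under ``cfg.seed`` (unless an external ``rng`` is passed).
    Spike-in positions must lie inside the panel.
    """
    for s in cfg.spike_ins:
        if not panel.contains(s.chrom, s.pos):
            raise ValueError(f"spike-in {s.chrom}:{s.pos} outside panel")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    truth = TruthManifest(seed=cfg.seed)
    n_mol = cfg.molecule_count()

    intervals = list(panel)
    weights = np.array([len(iv) for iv in intervals], dtype=float)
    weights /= weights.sum()
    iv_choice = rng.choice(len(intervals), size=n_mol, p=weights)

    geo_p = 1.0 / cfg.family_size_mean
    reads: list[TaggedRead] = []
    alt_mol = {i: 0 for i in range(len(cfg.spike_ins))}
    cov_mol = {i: 0 for i in range(len(cfg.spike_ins))}

    for mi in range(n_mol):
        iv = intervals[iv_choice[mi]]
        chrom_seq = reference[iv.chrom]
        jitter = int(rng.integers(-cfg.fragment_jitter, cfg.fragment_jitter + 1))
        frag_len = max(30, cfg.fragment_length + jitter)
        lo = max(0, iv.start - frag_len + 1)
        hi = max(lo + 1, min(iv.end, len(chrom_seq) - frag_len + 1))
        start = int(rng.integers(lo, hi))
        frag_len = min(frag_len, len(chrom_seq) - start)
        strand = "+" if rng.random() < 0.5 else "-"
        tag = _random_tag(rng, cfg.tag_length)

        hap = np.frombuffer(
            chrom_seq[start : start + frag_len].encode(), dtype=np.uint8
        ).copy()
        carried = []
        for vi, s in enumerate(cfg.spike_ins):
            if s.chrom == iv.chrom and start <= s.pos < start + frag_len:
                cov_mol[vi] += 1
                if rng.random() < s.vaf:
                    hap[s.pos - start] = ord(s.alt)
                    alt_mol[vi] += 1
                    carried.append(vi)

        n_reads = int(rng.geometric(geo_p))  # geometric support {1,2,...}
        mol_idx = len(truth.molecules)
        truth.molecules.append(
            {
                "tag": tag,
                "chrom": iv.chrom,
                "start": start,
                "strand": strand,
                "length": int(frag_len),
                "carries": carried,
                "n_reads": n_reads,
            }
        )
        for ri in range(n_reads):
            seq, n_err = _mutate_bases(hap, rng, cfg.raw_substitution_rate)
            cigar = f"{frag_len}M"
            n_indel = int(rng.binomial(frag_len, cfg.raw_indel_rate))
            for _ in range(n_indel):
                seq, cigar = _inject_indel(seq, rng)
            read_tag_arr, tag_err = _mutate_bases(
                np.frombuffer(tag.encode(), dtype=np.uint8), rng, cfg.tag_error_rate
            )
            read_tag = read_tag_arr.tobytes().decode()
            rid = f"m{mol_idx}r{ri}"
            reads.append(
                TaggedRead(
                    read_id=rid,
                    tag=read_tag,
                    chrom=iv.chrom,
                    start=start,
                    strand=strand,
                    cigar=cigar,
                    bases=seq.tobytes().decode(),
                    quals=[30] * seq.size,
                )
            )
            truth.reads.append(
                {"read_id": rid, "molecule": mol_idx, "n_sub_errors": n_err,
                 "n_indel_errors": n_indel, "n_tag_errors": tag_err}
            )
            truth.n_injected_errors += n_err

    for vi, s in enumerate(cfg.spike_ins):
        if s.vaf > 0:
            truth.variants.append(
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "nominal_vaf": s.vaf,
                    "alt_molecules": alt_mol[vi],
                    "covering_molecules": cov_mol[vi],
                    "realized_vaf": alt_mol[vi] / cov_mol[vi] if cov_mol[vi] else 0.0,
                }
            )
    return reads, truth


def as_raw_read(read: TaggedRead, spec: AdapterSpec) -> RawRead:
    """Recompose the pre-extraction view: tag + insert + duplex adapter."""
    return RawRead(
        read_id=read.read_id,
        chrom=read.chrom,
        start=read.start,
        strand=read.strand,
        bases=read.tag + read.bases + spec.duplex_adapter_seq,
        quals=[30] * len(read.tag) + read.quals + [30] * len(spec.duplex_adapter_seq),
        cigar=read.cigar,
    )


def sample_seed(master_seed: int, index: int) -> int:
    """Stable per-sample seed below 2^31 derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    cfg: SimulationConfig,
    panel: Panel,
    reference: Mapping[str, str],
    outdir: str,
    n_normals: int = 60,
    spike_series: Sequence[float] = SPIKE_LEVELS,
    duplicates: int = 2,
) -> dict:
    """Write a normal cohort plus a spike-in dilution series (with duplicates).

    Returns a manifest dict listing every written file; per-sample seeds are
    derived deterministically from ``cfg.seed``.
    """
    if n_normals < 1:
        raise ValueError("n_normals must be >= 1")
    os.makedirs(outdir, exist_ok=True)
    files = {"normals": [], "spikes": []}
    idx = 0
    for i in range(n_normals):
        scfg = _with(cfg, seed=sample_seed(cfg.seed, idx), spike_ins=[])
        idx += 1
        reads, truth = simulate_sample(scfg, panel, reference)
        stem = os.path.join(outdir, f"normal_{i:03d}")
        _emit(stem, reads, truth, files["normals"])
    for level in spike_series:
        spikes = [
            SpikeIn(s.chrom, s.pos, s.ref, s.alt, level) for s in cfg.spike_ins
        ]
        for rep in range(duplicates):
            scfg = _with(cfg, seed=sample_seed(cfg.seed, idx), spike_ins=spikes)
            idx += 1
            reads, truth = simulate_sample(scfg, panel, reference)
            stem = os.path.join(outdir, f"spike_{level:g}_rep{rep}")
            _emit(stem, reads, truth, files["spikes"])
    meta = {
        "master_seed": cfg.seed,
        "n_normals": n_normals,
        "spike_series": list(spike_series),
        "duplicates": duplicates,
        "files": files,
    }
    with open(os.path.join(outdir, "dataset.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta


def _with(cfg: SimulationConfig, **kw) -> SimulationConfig:
    d = asdict(cfg)
    d["spike_ins"] = list(cfg.spike_ins)
    d.update(kw)
    return SimulationConfig(**d)


def _emit(stem: str, reads, truth, bucket: list) -> None:
    from .tagio import write_tagged_reads

    reads_path = stem + ".reads.tsv"
    truth_path = stem + ".truth.json"
    if os.path.exists(reads_path):
        raise FileExistsError(reads_path)
    write_tagged_reads(reads, reads_path)
    truth.save(truth_path)
    bucket.append({"reads": reads_path, "truth": truth_path})


# ---------------------------------------------------------------------------
# consensus-level simulation

def simulate_sscs_pileup(
    panel: Panel,
    reference: Mapping[str, str],
    coverage: int,
    error_rate: float,
    rng: np.random.Generator,
    spike_ins: Sequence[SpikeIn] = (),
) -> SSCSPileup:
    """Draw an SSCS pileup directly at consensus level.

    At every panel position the consensus coverage is ``coverage`` split
    binomially between strands; each non-reference base receives
    Binomial(coverage, error_rate / 3) error molecules, and spike-in
    positions additionally receive Binomial(coverage, vaf) alt molecules.
    Positions are independent — adequate for caller/profile experiments, not
    for family-structure ones.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    spikes = {(s.chrom, s.pos): s for s in spike_ins}
    pileup = SSCSPileup(panel, reference)
    for (chrom, pos), ref in pileup.ref.items():
        cov_f = int(rng.binomial(coverage, 0.5))
        cov_r = coverage - cov_f
        remaining = [cov_f, cov_r]
        counts: dict[str, list[int]] = {}
        for alt in "ACGT":
            if alt == ref:
                continue
            k = int(rng.binomial(coverage, error_rate / 3))
            s = spikes.get((chrom, pos))
            if s is not None and s.alt == alt and s.vaf > 0:
                k += int(rng.binomial(coverage, s.vaf))
            if k == 0:
                continue
            k = min(k, coverage)
            kf = int(rng.hypergeometric(cov_f, cov_r, k)) if k else 0
            kf = min(kf, remaining[0])
            kr = min(k - kf, remaining[1])
            remaining[0] -= kf
            remaining[1] -= kr
            if kf or kr:
                counts[alt] = [kf, kr]
        counts[ref] = [remaining[0], remaining[1]]
        pileup.counts[(chrom, pos)] = counts
    pileup.n_sscs = coverage
    return pileup
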
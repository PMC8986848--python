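"""Family building and single-strand consensus collapsing.

Reads sharing one (molecular tag, alignment start, strand) key are assumed to
derive from the same original cfDNA strand.  Each family is collapsed into a
single-strand consensus sequence (SSCS): at every reference position an
allele is kept only when it is carried by strictly more than a configurable
majority (default 70%) of the family members covering that position;
otherwise the consensus is N.  Deletions and insertions are voted by the same
rule.  Consensus sequences are then accumulated into a per-position,
per-allele, per-strand pileup over the target panel.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .regions import Panel
from .tagio import FORWARD, REVERSE, TaggedRead, parse_cigar

BASES = ("A", "C", "G", "T")
# pileup allele order in the TSV export
_TSV_ALLELES = ("A", "C", "G", "T", "del", "ins")


@dataclass(frozen=True, order=True)
class FamilyKey:
    tag: str
    chrom: str
    start: int
    strand: str


@dataclass
class ReadFamily:
    key: FamilyKey
    members: list[TaggedRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusConfig:
    """Knobs of the collapsing stage.

    majority_threshold is a strict lower bound on the within-family allele
    fraction: at exactly the threshold the position is called N.
    """

    majority_threshold: float = 0.70
    min_family_size: int = 1
    tag_merge_hamming: int = 1

    def __post_init__(self) -> None:
        if not (0.5 <= self.majority_threshold < 1):
            raise ValueError("majority_threshold must be in [0.5, 1)")
        if self.min_family_size < 1:
            raise ValueError("min_family_size must be >= 1")

    @property
    def threshold_fraction(self) -> Fraction:
        # exact arithmetic so the 70.0% boundary is handled without float fuzz
        return Fraction(self.majority_threshold).limit_denominator(10_000)


@dataclass
class SSCSRecord:
    """One consensus molecule.

    ``bases`` spans [key.start, key.start + len(bases)) on the reference; N
    marks positions with no majority allele and positions inside a consensus
    deletion (the deletion itself is listed in ``indels``).  ``indels`` holds
    ``("del", pos, length)`` and ``("ins", pos, seq)`` events, the latter
    anchored at the reference position immediately left of the insertion.
    """

    key: FamilyKey
    bases: str
    family_size: int
    indels: list[tuple] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.key.start

    @property
    def end(self) -> int:
        return self.key.start + len(self.bases)


@dataclass
class FamilyRejected:
    key: FamilyKey
    reason: str


def build_families(reads: Iterable[TaggedRead]) -> list[ReadFamily]:
    """Partition reads into families keyed by (tag, chrom, start, strand)."""
    buckets: dict[FamilyKey, list[TaggedRead]] = defaultdict(list)
    for r in reads:
        buckets[FamilyKey(r.tag, r.chrom, r.start, r.strand)].append(r)
    fams = []
    for key in sorted(buckets):
        members = sorted(buckets[key], key=lambda r: r.read_id)
        fams.append(ReadFamily(key, members))
    return fams


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def merge_tag_neighbors(
    families: list[ReadFamily], max_hamming: int = 1
) -> list[ReadFamily]:
    """Absorb small families into tag-neighbouring larger ones at the same locus.

    Directional, largest-first: within one (chrom, start, strand) locus a
    family is absorbed by the largest already-accepted family whose tag is
    within ``max_hamming`` and whose original size is strictly larger (ties
    on size broken by lexicographically smaller tag).  This removes spurious
    families created by sequencing errors inside the molecular tag.
    """
    if max_hamming < 1:
        return families
    by_locus: dict[tuple, list[ReadFamily]] = defaultdict(list)
    for f in families:
        by_locus[(f.key.chrom, f.key.start, f.key.strand)].append(f)

    out: list[ReadFamily] = []
    for locus in sorted(by_locus):
        fams = sorted(by_locus[locus], key=lambda f: (-f.size, f.key.tag))
        orig_size = {f.key.tag: f.size for f in fams}
        winners: list[ReadFamily] = []
        for f in fams:
            # winners are in (-size, tag) order, so the first match is the
            # largest candidate with the lexicographically smallest tag
            best = None
            for w in winners:
                if (
                    orig_size[w.key.tag] > orig_size[f.key.tag]
                    and _hamming(w.key.tag, f.key.tag) <= max_hamming
                ):
                    best = w
                    break
            if best is None:
                winners.append(ReadFamily(f.key, list(f.members)))
            else:
                best.members.extend(f.members)
        for w in winners:
            w.members.sort(key=lambda r: r.read_id)
        out.extend(winners)
    out.sort(key=lambda f: f.key)
    return out


def _read_alleles(read: TaggedRead) -> tuple[dict[int, str], dict[int, str]]:
    """Map reference positions covered by a read to its allele there.

    Returns (per-position base or 'del', insertions anchored left).
    """
    alleles: dict[int, str] = {}
    inserts: dict[int, str] = {}
    rpos = read.start
    qpos = 0
    for op, n in parse_cigar(read.cigar):
        if op in "M=X":
            for i in range(n):
                alleles[rpos + i] = read.bases[qpos + i]
            rpos += n
            qpos += n
        elif op == "D":
            for i in range(n):
                alleles[rpos + i] = "del"
            rpos += n
        elif op == "I":
            if rpos > read.start:
                inserts[rpos - 1] = read.bases[qpos : qpos + n]
            qpos += n
        elif op == "S":
            qpos += n
        elif op == "N":
            rpos += n
        # H and P consume nothing we track
    return alleles, inserts


def _collapse_fast(family: ReadFamily, thr: Fraction) -> SSCSRecord:
    """Vectorized vote for the common case: identical-length all-match reads."""
    n = family.size
    L = len(family.members[0].bases)
    mat = np.frombuffer(
        "".join(r.bases for r in family.members).encode(), dtype=np.uint8
    ).reshape(n, L)
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in BASES])
    best = counts.argmax(axis=0)
    bestc = counts.max(axis=0)
    # strict majority: count/n > thr  <=>  count*thr.den > thr.num*n
    win = bestc * thr.denominator > thr.numerator * n
    out = np.where(win, np.array([ord(b) for b in BASES], dtype=np.uint8)[best], ord("N"))
    return SSCSRecord(family.key, out.tobytes().decode(), n, [])


def collapse_family(
    family: ReadFamily, cfg: ConsensusConfig = ConsensusConfig()
) -> SSCSRecord | FamilyRejected:
    """Collapse one read family into its single-strand consensus.

    Families smaller than ``min_family_size`` are rejected (a tagged outcome,
    not an error).  A family of one yields the read verbatim.
    """
    if family.size < cfg.min_family_size:
        return FamilyRejected(family.key, "family_too_small")
    thr = cfg.threshold_fraction

    first_cigar = family.members[0].cigar
    if (
        all(r.cigar == first_cigar for r in family.members)
        and set(op for op, _ in parse_cigar(first_cigar)) == {"M"}
        and len({len(r.bases) for r in family.members}) == 1
    ):
        return _collapse_fast(family, thr)

    per_read = [_read_alleles(r) for r in family.members]
    span_start = family.key.start
    span_end = max(max(a) + 1 for a, _ in per_read if a)

    base_votes: dict[int, Counter] = defaultdict(Counter)
    ins_votes: dict[int, Counter] = defaultdict(Counter)
    covering: Counter = Counter()
    for alleles, inserts in per_read:
        for pos, al in alleles.items():
            covering[pos] += 1
            base_votes[pos][al] += 1
        for pos, seq in inserts.items():
            ins_votes[pos][seq] += 1

    out = []
    del_runs: list[tuple] = []
    run_start = None
    for pos in range(span_start, span_end):
        cov = covering.get(pos, 0)
        winner = "N"
        if cov:
            al, cnt = base_votes[pos].most_common(1)[0]
            if Fraction(cnt, cov) > thr:
                winner = al
        if winner == "del":
            out.append("N")
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None:
                del_runs.append(("del", run_start, pos - run_start))
                run_start = None
            out.append(winner)
    if run_start is not None:
        del_runs.append(("del", run_start, span_end - run_start))

    indels = list(del_runs)
    for pos in sorted(ins_votes):
        cov = covering.get(pos, 0)
        if not cov:
            continue
        seq, cnt = ins_votes[pos].most_common(1)[0]
        if Fraction(cnt, cov) > thr:
            indels.append(("ins", pos, seq))
    indels.sort(key=lambda e: (e[1], e[0]))
    return SSCSRecord(family.key, "".join(out), family.size, indels)


def collapse_all(
    families: Iterable[ReadFamily], cfg: ConsensusConfig = ConsensusConfig()
) -> tuple[list[SSCSRecord], list[FamilyRejected]]:
    records, rejected = [], []
    for fam in families:
        res = collapse_family(fam, cfg)
        if isinstance(res, SSCSRecord):
            records.append(res)
        else:
            rejected.append(res)
    return records, rejected


# ---------------------------------------------------------------------------
# Pileup

def ref_base(reference: Mapping[str, str], chrom: str, pos: int) -> str:
    """Reference base lookup working for both dict-of-strings and pyfaidx.Fasta."""
    if chrom not in reference:
        raise KeyError(f"contig {chrom!r} absent from reference")
    return str(reference[chrom][pos]).upper()


class SSCSPileup:
    """Per-position, per-allele, per-strand counts at consensus level.

    Substitution and deletion alleles are counted per position; ``coverage``
    at a position is the total over {A,C,G,T,del} on both strands.  Insertion
    events sit between positions: they are tracked in ``indel_events`` (and
    the ins_f/ins_r export columns) but excluded from coverage.  N consensus
    bases contribute to nothing.
    """

    STRAND_IDX = {FORWARD: 0, REVERSE: 1}

    def __init__(self, panel: Panel, reference: Mapping[str, str]):
        self.panel = panel
        for chrom in panel.chroms:
            if chrom not in reference:
                raise KeyError(f"panel contig {chrom!r} absent from reference")
        self.ref: dict[tuple[str, int], str] = {
            (c, p): ref_base(reference, c, p) for c, p in panel.positions()
        }
        # (chrom,pos) -> {allele: [fwd, rev]}
        self.counts: dict[tuple[str, int], dict[str, list[int]]] = {
            site: {} for site in self.ref
        }
        # (chrom, pos, descriptor) -> [fwd, rev]; descriptor "del:<len>"/"ins:<seq>"
        self.indel_events: dict[tuple[str, int, str], list[int]] = {}
        self.n_sscs = 0

    # -- accumulation -----------------------------------------------------

    def _bump(self, chrom: str, pos: int, allele: str, strand: str, by: int = 1) -> None:
        site = (chrom, pos)
        if site not in self.counts:
            return  # outside panel
        slot = self.counts[site].setdefault(allele, [0, 0])
        slot[self.STRAND_IDX[strand]] += by

    def add_sscs(self, rec: SSCSRecord) -> None:
        chrom, strand = rec.key.chrom, rec.key.strand
        deleted = set()
        for kind, pos, arg in rec.indels:
            if kind == "del":
                length = int(arg)
                for p in range(pos, pos + length):
                    deleted.add(p)
                    self._bump(chrom, p, "del", strand)
                key = (chrom, pos, f"del:{length}")
                if (chrom, pos) in self.counts:
                    self.indel_events.setdefault(key, [0, 0])[
                        self.STRAND_IDX[strand]
                    ] += 1
            else:  # ins
                key = (chrom, pos, f"ins:{arg}")
                if (chrom, pos) in self.counts:
                    self.indel_events.setdefault(key, [0, 0])[
                        self.STRAND_IDX[strand]
                    ] += 1
        for i, b in enumerate(rec.bases):
            pos = rec.start + i
            if b == "N" or pos in deleted:
                continue
            self._bump(chrom, pos, b, strand)
        self.n_sscs += 1

    def add_all(self, records: Iterable[SSCSRecord]) -> "SSCSPileup":
        for rec in records:
            self.add_sscs(rec)
        return self

    # -- queries ----------------------------------------------------------

    def coverage(self, chrom: str, pos: int) -> int:
        return sum(f + r for f, r in self.counts.get((chrom, pos), {}).values())

    def strand_coverage(self, chrom: str, pos: int) -> tuple[int, int]:
        cnts = self.counts.get((chrom, pos), {})
        return (
            sum(v[0] for v in cnts.values()),
            sum(v[1] for v in cnts.values()),
        )

    def allele_counts(self, chrom: str, pos: int, allele: str) -> tuple[int, int]:
        v = self.counts.get((chrom, pos), {}).get(allele, [0, 0])
        return v[0], v[1]

    def sites(self):
        return self.ref.keys()

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, pos), ref in self.ref.items():
            cnts = self.counts[(chrom, pos)]
            row = {"chrom": chrom, "pos": pos + 1, "ref": ref}
            for al in ("A", "C", "G", "T", "del"):
                f, r = cnts.get(al, (0, 0))
                row[f"{al if al != 'del' else 'del'}_f"] = f
                row[f"{al if al != 'del' else 'del'}_r"] = r
            ins_f = ins_r = 0
            for (c, p, desc), (f, r) in self.indel_events.items():
                if c == chrom and p == pos and desc.startswith("ins:"):
                    ins_f += f
                    ins_r += r
            row["ins_f"], row["ins_r"] = ins_f, ins_r
            row["coverage"] = self.coverage(chrom, pos)
            rows.append(row)
        cols = ["chrom", "pos", "ref"] + [
            f"{a}_{s}" for a in _TSV_ALLELES for s in ("f", "r")
        ] + ["coverage"]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path: str, events_path: Optional[str] = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if events_path is None:
            events_path = path + ".events"
        with open(events_path, "w") as fh:
            fh.write("chrom\tpos\tdescriptor\tcount_f\tcount_r\n")
            for (chrom, pos, desc) in sorted(self.indel_events):
                f, r = self.indel_events[(chrom, pos, desc)]
                fh.write(f"{chrom}\t{pos + 1}\t{desc}\t{f}\t{r}\n")

    @classmethod
    def from_tsv(
        cls, path: str, events_path: Optional[str] = None
    ) -> "SSCSPileup":
        from .regions import Interval

        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        ivs = [
            Interval(chrom, int(pos) - 1, int(pos))
            for chrom, pos in zip(df["chrom"], df["pos"])
        ]
        ref = {
            (chrom, int(pos) - 1): rb
            for chrom, pos, rb in zip(df["chrom"], df["pos"], df["ref"])
        }
        obj = cls.__new__(cls)
        obj.panel = Panel(ivs)
        obj.ref = ref
        obj.counts = {site: {} for site in ref}
        obj.indel_events = {}
        obj.n_sscs = 0
        for _, row in df.iterrows():
            site = (row["chrom"], int(row["pos"]) - 1)
            for al in ("A", "C", "G", "T", "del"):
                f, r = int(row[f"{al}_f"]), int(row[f"{al}_r"])
                if f or r:
                    obj.counts[site][al] = [f, r]
        if events_path is None:
            events_path = path + ".events"
        try:
            ev = pd.read_csv(events_path, sep="\t", dtype={"chrom": str})
        except FileNotFoundError:
            ev = None
        if ev is not None:
            for _, row in ev.iterrows():
                obj.indel_events[
                    (row["chrom"], int(row["pos"]) - 1, row["descriptor"])
                ] = [int(row["count_f"]), int(row["count_r"])]
        return obj


def build_pileup(
    sscs: Iterable[SSCSRecord], panel: Panel, reference: Mapping[str, str]
) -> SSCSPileup:
    """Accumulate consensus records into a panel-restricted pileup."""
    return SSCSPileup(panel, reference).add_all(sscs)
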
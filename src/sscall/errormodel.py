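"""Background error profile from mutation-free control samples.

For every panel position and alternative allele, alt-supporting consensus
counts (k) and consensus coverage (n) are pooled across a cohort of control
plasma samples.  Because tag-based consensus leaves many positions entirely
error-free even across dozens of controls, the profile does not use the
maximum-likelihood rate k/n directly: it stores a conservative upper
confidence bound ε_up on the true per-molecule error rate, which is strictly
positive even at k = 0.  Larger control cohorts shrink the bound toward the
real error profile.

Three bound constructions are available (``ProfileConfig.method``):

``kl`` (default)
    Invert the Chernoff/Kullback–Leibler binomial tail bound: the largest ε
    with n·KL(k/n ‖ ε) ≤ ln(1/δ).  At k = 0 this equals 1 − δ^(1/n) ≈
    ln(1/δ)/n, the same rate as the exact binomial (Clopper–Pearson) bound.
``hoeffding``
    The additive sub-Gaussian bound k/n + sqrt(ln(1/δ)/(2n)).  Simple and
    distribution-free, but far looser at small rates: its floor ~n^(-1/2)
    dominates realistic consensus error rates unless n is astronomically
    large, making it unsuitable as a default for rare-variant calling.
``clopper-pearson``
    The exact binomial upper confidence limit at level 1 − δ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta

from .consensus import BASES, SSCSPileup
from .regions import PositionMask

METHODS = ("kl", "hoeffding", "clopper-pearson")


@dataclass(frozen=True)
class ProfileConfig:
    """Parameters of the error-profile construction.

    delta is the per-(position, allele) confidence level of the upper bound;
    strands are pooled by default (strand balance is the caller's job) to
    maximize n per entry.  Indel background entries are keyed by indel length
    class, not exact sequence, to keep n usable.
    """

    delta: float = 0.01
    pool_strands: bool = True
    method: str = "kl"
    snp_mask: Optional[PositionMask] = None

    def __post_init__(self) -> None:
        if not (0 < self.delta < 1):
            raise ValueError("delta must be in (0, 1)")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


@dataclass
class ErrorProfileEntry:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str  # base, or "del:<len>" / "ins:<len>" length class
    k: int
    n: int
    epsilon_up: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")


def _kl_bernoulli(p: float, q: float) -> float:
    if q <= 0 or q >= 1:
        return math.inf if p != q else 0.0
    out = 0.0
    if p > 0:
        out += p * math.log(p / q)
    if p < 1:
        out += (1 - p) * math.log((1 - p) / (1 - q))
    return out


def massart_upper_bound(
    k: int, n: int, delta: float = 0.01, method: str = "kl"
) -> float:
    """Conservative upper confidence bound on a binomial proportion.

    Returns ε_up ≥ k/n such that observing ≤ k events in n trials would be a
    ≤ δ probability event at any true rate above ε_up.  ε_up > 0 even at
    k = 0.  Raises on n = 0 ("no_coverage": the position is not testable).
    """
    if n < 1:
        raise ValueError("no_coverage")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    phat = k / n
    target = math.log(1.0 / delta)
    if method == "hoeffding":
        return min(1.0, phat + math.sqrt(target / (2 * n)))
    if method == "clopper-pearson":
        if k == n:
            return 1.0
        return float(beta.ppf(1 - delta, k + 1, n - k))
    if method == "kl":
        if phat >= 1.0:
            return 1.0
        f = lambda q: n * _kl_bernoulli(phat, q) - target
        hi = 1.0 - 1e-12
        if f(hi) <= 0:
            return 1.0
        lo = max(phat, 1e-300)
        if f(lo) >= 0:  # only at degenerate deltas
            return phat
        return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-12))
    raise ValueError(f"unknown method {method!r}")


def _indel_length_class(descriptor: str) -> str:
    kind, arg = descriptor.split(":", 1)
    length = int(arg) if kind == "del" else len(arg)
    return f"{kind}:{length}"


def accumulate_background(
    control_pileups: list[SSCSPileup], snp_mask: Optional[PositionMask] = None
) -> dict[tuple[str, int, str, str], tuple[int, int]]:
    """Pool alt counts and coverage over control samples.

    Returns {(chrom, pos, ref, alt): (k, n)} for every non-masked panel
    position with n > 0; alt covers the three non-reference bases, per-position
    deletion, and observed indel length classes.  All controls must share one
    panel.
    """
    if not control_pileups:
        raise ValueError("need at least one control pileup")
    sites = list(control_pileups[0].sites())
    checks = {p.panel.checksum() for p in control_pileups}
    if len(checks) != 1:
        raise ValueError("control pileups cover different panels")

    out: dict[tuple[str, int, str, str], tuple[int, int]] = {}
    for chrom, pos in sites:
        if snp_mask is not None and (chrom, pos) in snp_mask:
            continue
        ref = control_pileups[0].ref[(chrom, pos)]
        n = 0
        ks: dict[str, int] = {}
        for p in control_pileups:
            n += p.coverage(chrom, pos)
            for alt in BASES:
                if alt == ref:
                    continue
                f, r = p.allele_counts(chrom, pos, alt)
                ks[alt] = ks.get(alt, 0) + f + r
            f, r = p.allele_counts(chrom, pos, "del")
            ks["del"] = ks.get("del", 0) + f + r
        if n == 0:
            continue
        for alt in BASES:
            if alt != ref:
                out[(chrom, pos, ref, alt)] = (ks.get(alt, 0), n)
        # per-position deletion channel kept as a generic length-1 class;
        # longer classes come from the event tables below
        ilens: dict[str, int] = {}
        for p in control_pileups:
            for (c, q, desc), (f, r) in p.indel_events.items():
                if c == chrom and q == pos:
                    cls = _indel_length_class(desc)
                    ilens[cls] = ilens.get(cls, 0) + f + r
        for cls, k in ilens.items():
            out[(chrom, pos, ref, cls)] = (k, n)
    return out


class ErrorProfile:
    """The per-(position, alt) background table plus its construction metadata."""

    def __init__(
        self,
        entries: list[ErrorProfileEntry],
        delta: float,
        method: str,
        panel_checksum: str,
        n_controls: int,
    ):
        self.entries = entries
        self.delta = delta
        self.method = method
        self.panel_checksum = panel_checksum
        self.n_controls = n_controls
        self._index = {
            (e.chrom, e.pos, e.alt): e for e in entries
        }

    def lookup(self, chrom: str, pos: int, alt: str) -> Optional[ErrorProfileEntry]:
        if alt.startswith(("del:", "ins:")):
            alt = _indel_length_class(alt)
        return self._index.get((chrom, pos, alt))

    def positions(self) -> set[tuple[str, int]]:
        return {(e.chrom, e.pos) for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": e.chrom,
                    "pos": e.pos + 1,
                    "ref": e.ref,
                    "alt": e.alt,
                    "k": e.k,
                    "n": e.n,
                    "epsilon_up": e.epsilon_up,
                }
                for e in self.entries
            ],
            columns=["chrom", "pos", "ref", "alt", "k", "n", "epsilon_up"],
        )

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        with open(path + ".json", "w") as fh:
            json.dump(
                {
                    "delta": self.delta,
                    "method": self.method,
                    "panel_checksum": self.panel_checksum,
                    "n_controls": self.n_controls,
                    "tool": "sscall",
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: str) -> "ErrorProfile":
        df = pd.read_csv(
            path, sep="\t", dtype={"chrom": str, "alt": str},
            float_precision="round_trip",
        )
        with open(path + ".json") as fh:
            meta = json.load(fh)
        entries = [
            ErrorProfileEntry(
                chrom=row["chrom"],
                pos=int(row["pos"]) - 1,
                ref=row["ref"],
                alt=row["alt"],
                k=int(row["k"]),
                n=int(row["n"]),
                epsilon_up=float(row["epsilon_up"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(
            entries,
            delta=meta["delta"],
            method=meta["method"],
            panel_checksum=meta["panel_checksum"],
            n_controls=meta["n_controls"],
        )


def build_error_profile(
    controls: list[SSCSPileup], cfg: ProfileConfig = ProfileConfig()
) -> ErrorProfile:
    """Build the background profile from ≥ 1 control pileups."""
    if not controls:
        raise ValueError("need at least one control sample")
    bg = accumulate_background(controls, cfg.snp_mask)
    entries = [
        ErrorProfileEntry(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            k=k,
            n=n,
            epsilon_up=massart_upper_bound(k, n, cfg.delta, cfg.method),
        )
        for (chrom, pos, ref, alt), (k, n) in sorted(bg.items())
    ]
    return ErrorProfile(
        entries,
        delta=cfg.delta,
        method=cfg.method,
        panel_checksum=controls[0].panel.checksum(),
        n_controls=len(controls),
    )
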
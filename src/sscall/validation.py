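"""Desk-scale validation experiments: specificity and spike-in sensitivity.

These reproduce the assay's validation design at consensus level: an error
profile is trained on one cohort of simulated mutation-free normals, and
either held-out mutation-free samples (specificity) or spike-in dilution
duplicates (sensitivity) are called against it.  Scale defaults mirror the
published operating point: 60 training normals, 60 held-out samples, SSCS
coverage ~2000 per position, per-molecule consensus error rate ~1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caller import CallerConfig, call_variants
from .errormodel import ProfileConfig, build_error_profile
from .simulate import (
    SpikeIn,
    default_panel,
    make_reference,
    sample_seed,
    simulate_sscs_pileup,
)


@dataclass
class SpecificityResult:
    n_samples: int
    tested_hypotheses: int
    false_pass_hypotheses: int
    clean_samples: int
    false_calls: list = field(default_factory=list)

    @property
    def variant_specificity_pct(self) -> float:
        """% of tested (position, alt) hypotheses without a false PASS call."""
        if self.tested_hypotheses == 0:
            return 100.0
        return 100.0 * (1 - self.false_pass_hypotheses / self.tested_hypotheses)

    @property
    def sample_specificity_pct(self) -> float:
        """% of held-out mutation-free samples with zero PASS calls."""
        return 100.0 * self.clean_samples / self.n_samples


def _world(seed: int, panel_bp: int):
    reference = make_reference({"chr1": 2000}, seed=sample_seed(seed, 9000))
    panel = default_panel(reference, panel_bp)
    return reference, panel


def train_profile(
    seed: int,
    n_train: int = 60,
    coverage: int = 2000,
    error_rate: float = 1e-4,
    panel_bp: int = 300,
    delta: float = 0.01,
):
    """Build a background profile from ``n_train`` simulated normals."""
    reference, panel = _world(seed, panel_bp)
    controls = [
        simulate_sscs_pileup(
            panel, reference, coverage, error_rate,
            np.random.default_rng(sample_seed(seed, i)),
        )
        for i in range(n_train)
    ]
    profile = build_error_profile(controls, ProfileConfig(delta=delta))
    return profile, panel, reference


def specificity_experiment(
    seed: int = 1,
    n_train: int = 60,
    n_test: int = 60,
    coverage: int = 2000,
    error_rate: float = 1e-4,
    panel_bp: int = 300,
    caller_cfg: CallerConfig = CallerConfig(),
) -> SpecificityResult:
    """Call held-out mutation-free samples against an independent profile."""
    profile, panel, reference = train_profile(
        seed, n_train, coverage, error_rate, panel_bp
    )
    tested = false_pass = clean = 0
    false_calls = []
    for j in range(n_test):
        rng = np.random.default_rng(sample_seed(seed, 1000 + j))
        pileup = simulate_sscs_pileup(panel, reference, coverage, error_rate, rng)
        calls, universe = call_variants(pileup, profile, caller_cfg)
        passed = [c for c in calls if c.passed]
        tested += universe.m
        false_pass += len(passed)
        clean += not passed
        false_calls.extend(
            {"sample": j, "chrom": c.chrom, "pos": c.pos, "alt": c.alt,
             "vaf": c.vaf, "p_adj": c.p_adj}
            for c in passed
        )
    return SpecificityResult(
        n_samples=n_test,
        tested_hypotheses=tested,
        false_pass_hypotheses=false_pass,
        clean_samples=clean,
        false_calls=false_calls,
    )


def sensitivity_experiment(
    seed: int = 1,
    vaf: float = 0.005,
    n_variants: int = 6,
    duplicates: int = 2,
    n_train: int = 60,
    coverage: int = 2000,
    error_rate: float = 1e-4,
    panel_bp: int = 300,
    caller_cfg: CallerConfig = CallerConfig(),
) -> dict:
    """Spike ``n_variants`` variants at ``vaf`` into duplicate samples and call.

    Returns per-duplicate detection counts and the planted variant list.
    """
    profile, panel, reference = train_profile(
        seed, n_train, coverage, error_rate, panel_bp
    )
    positions = list(panel.positions())
    step = max(1, len(positions) // (n_variants + 1))
    spikes = []
    for v in range(n_variants):
        chrom, pos = positions[(v + 1) * step]
        ref_base = reference[chrom][pos]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_base]
        spikes.append(SpikeIn(chrom, pos, ref_base, alt, vaf))

    detected_per_dup = []
    for d in range(duplicates):
        rng = np.random.default_rng(sample_seed(seed, 5000 + d))
        pileup = simulate_sscs_pileup(
            panel, reference, coverage, error_rate, rng, spikes
        )
        calls, _ = call_variants(pileup, profile, caller_cfg)
        passed = {(c.chrom, c.pos, c.alt) for c in calls if c.passed}
        detected = sum(
            (s.chrom, s.pos, s.alt) in passed for s in spikes
        )
        detected_per_dup.append(detected)
    return {
        "n_variants": n_variants,
        "duplicates": duplicates,
        "vaf": vaf,
        "detected_per_duplicate": detected_per_dup,
        "spikes": [(s.chrom, s.pos, s.ref, s.alt) for s in spikes],
    }
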
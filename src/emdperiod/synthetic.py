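"""Synthetic expression profiles with known periodicity ground truth.

The generator emulates the structure of metabolic-cycle microarray series:
a ~300-min sinusoid sampled every 25 min over 36 points, optionally masked
by a slow trend and a faster interfering oscillation, plus i.i.d. Gaussian
noise.  Three truth labels cover the cases the detection pipeline must
distinguish:

``PERIODIC_CLEAN``
    the target sinusoid with mild noise; the raw autocorrelation test
    should call it periodic.
``UNDER_DETECTED``
    the target sinusoid buried under a strong slow wave and a fast tone;
    the raw test should fail but some IMF-subset reconstruction should
    pass (the putative-periodic rescue scenario).
``NULL``
    pure Gaussian noise; nothing should be detected beyond the test level.

Every profile is a pure function of its spec (seed included), so datasets
are reproducible row by row regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from emdperiod.emd import ExpressionProfile, TimeGrid

__all__ = [
    "SyntheticSpec",
    "periodic_clean_spec",
    "under_detected_spec",
    "null_spec",
    "make_profile",
    "make_dataset",
    "make_complex_matrix",
]

PERIODIC_CLEAN = "PERIODIC_CLEAN"
UNDER_DETECTED = "UNDER_DETECTED"
NULL = "NULL"
_LABELS = (PERIODIC_CLEAN, UNDER_DETECTED, NULL)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic profile.

    x_t = A sin(2 pi t dt / period + phase) + trend(t)
          + F sin(2 pi t dt / fast_period + fast_phase) + N(0, sigma^2)

    ``phase=None`` draws the signal phase uniformly from the seed; the fast
    tone always gets its own random phase (at the default 50-min period —
    exactly the Nyquist frequency of 25-min sampling — a zero-phase sine
    vanishes identically at the sample times, so a random phase is what
    keeps the tone a genuine alternating oscillation).

    The slow-sine trend period defaults to 900 min: one full cycle across
    the 36-point window, slow enough to read as a trend yet oscillatory
    enough to interfere with the 300-min autocorrelation.
    """

    seed: int
    truth_label: str = PERIODIC_CLEAN
    n_points: int = 36
    interval: float = 25.0
    period: float = 300.0
    signal_amplitude: float = 1.0
    phase: float | None = None
    trend_type: str = "none"  # none | linear | quadratic | slow-sine
    trend_amplitude: float = 0.0
    trend_period: float = 900.0  # slow-sine only
    fast_amplitude: float = 0.0
    fast_period: float = 50.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.truth_label not in _LABELS:
            raise ValueError(f"unknown truth label {self.truth_label!r}")
        if self.trend_type not in ("none", "linear", "quadratic", "slow-sine"):
            raise ValueError(f"unknown trend_type {self.trend_type!r}")
        if self.truth_label == NULL:
            if self.signal_amplitude != 0:
                raise ValueError("NULL profiles must have zero signal amplitude")
            if self.noise_sd <= 0:
                raise ValueError("NULL profiles need positive noise")
        if self.truth_label == UNDER_DETECTED:
            masking = max(self.trend_amplitude, self.fast_amplitude)
            if masking <= self.signal_amplitude:
                raise ValueError(
                    "UNDER_DETECTED requires trend or fast-tone amplitude "
                    "above the signal amplitude"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.n_points, self.interval, self.period)


def periodic_clean_spec(seed: int, **overrides) -> SyntheticSpec:
    """Target sinusoid (A=1) with mild noise (sigma=0.1)."""
    return replace(
        SyntheticSpec(seed=seed, truth_label=PERIODIC_CLEAN, signal_amplitude=1.0, noise_sd=0.1),
        **overrides,
    )


def under_detected_spec(seed: int, **overrides) -> SyntheticSpec:
    """Masked sinusoid: slow-sine trend (amp 3), 50-min tone (amp 1.5), sigma=0.5."""
    return replace(
        SyntheticSpec(
            seed=seed,
            truth_label=UNDER_DETECTED,
            signal_amplitude=1.0,
            trend_type="slow-sine",
            trend_amplitude=3.0,
            trend_period=900.0,
            fast_amplitude=1.5,
            fast_period=50.0,
            noise_sd=0.5,
        ),
        **overrides,
    )


def null_spec(seed: int, **overrides) -> SyntheticSpec:
    """Pure Gaussian noise (sigma=1)."""
    return replace(
        SyntheticSpec(seed=seed, truth_label=NULL, signal_amplitude=0.0, noise_sd=1.0),
        **overrides,
    )


def _trend(spec: SyntheticSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a = spec.trend_amplitude
    if spec.trend_type == "none" or a == 0:
        return np.zeros_like(t)
    u = t / (spec.n_points - 1)  # 0..1 across the window
    if spec.trend_type == "linear":
        return a * (2.0 * u - 1.0)
    if spec.trend_type == "quadratic":
        return a * (2.0 * u - 1.0) ** 2
    # slow-sine
    phase = rng.uniform(0.0, 2.0 * math.pi)
    return a * np.sin(2.0 * math.pi * t * spec.interval / spec.trend_period + phase)


def make_profile(spec: SyntheticSpec, probeset_id: str | None = None) -> tuple[ExpressionProfile, dict]:
    """Generate one profile and its truth record.

    The truth record keeps the drawn phases and the noiseless latent signal
    so downstream tests can check which IMF captured it.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_points, dtype=float)
    phase = rng.uniform(0.0, 2.0 * math.pi) if spec.phase is None else float(spec.phase)
    signal = spec.signal_amplitude * np.sin(
        2.0 * math.pi * t * spec.interval / spec.period + phase
    )
    trend = _trend(spec, t, rng)
    fast_phase = rng.uniform(0.0, 2.0 * math.pi)
    fast = spec.fast_amplitude * np.sin(
        2.0 * math.pi * t * spec.interval / spec.fast_period + fast_phase
    )
    noise = rng.normal(0.0, spec.noise_sd, spec.n_points) if spec.noise_sd > 0 else 0.0
    values = signal + trend + fast + noise
    pid = probeset_id if probeset_id is not None else f"synth_{spec.truth_label}_{spec.seed}"
    truth = {
        "probeset_id": pid,
        "truth_label": spec.truth_label,
        "seed": spec.seed,
        "phase": phase,
        "fast_phase": fast_phase,
        "signal": signal,
    }
    return ExpressionProfile(probeset_id=pid, values=values), truth


def _child_seeds(base_seed: int, n: int) -> list[int]:
    # counter-based split: row k's seed never depends on the other rows
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


def make_dataset(
    n_periodic: int,
    n_underdetected: int,
    n_null: int,
    base_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (rows = profiles) plus a truth table.

    Rows are grouped by label: PERIODIC_CLEAN, then UNDER_DETECTED, then
    NULL.  Per-row seeds are split from ``base_seed`` by counter, so the
    values of any row are independent of how many other rows exist.
    """
    counts = (n_periodic, n_underdetected, n_null)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    factories = (periodic_clean_spec, under_detected_spec, null_spec)
    labels = (PERIODIC_CLEAN, UNDER_DETECTED, NULL)
    total = sum(counts)
    seeds = _child_seeds(base_seed, total)
    rows, truth_rows, ids = [], [], []
    k = 0
    for count, factory, label in zip(counts, factories, labels):
        for j in range(count):
            pid = f"{label}_{j:05d}"
            profile, truth = make_profile(factory(seeds[k]), probeset_id=pid)
            rows.append(profile.values)
            ids.append(pid)
            truth_rows.append(
                {"probeset_id": pid, "truth_label": label, "seed": seeds[k]}
            )
            k += 1
    n_points = SyntheticSpec(seed=0).n_points
    matrix = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(total, n_points),
        index=pd.Index(ids, name="probeset_id"),
        columns=[f"t{i+1}" for i in range(n_points)],
    )
    truth = pd.DataFrame(truth_rows, columns=["probeset_id", "truth_label", "seed"])
    return matrix, truth


def make_complex_matrix(
    n_complexes: int,
    genes_per_complex: int,
    n_background: int,
    noise_sd: float = 0.3,
    seed: int = 0,
    n_points: int = 36,
    interval: float = 25.0,
    period: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matrix with coexpressed blocks mirroring protein-complex structure.

    Each complex shares one latent periodic profile (unit-amplitude
    sinusoid at the target period, random phase); members are the latent
    plus independent Gaussian noise.  Background genes are independent
    standard-normal noise.  Returns the matrix and a membership table
    (complex_id, complex_name, gene_id).
    """
    if genes_per_complex < 2:
        raise ValueError("genes_per_complex must be at least 2")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float)
    rows, ids, members = [], [], []
    for c in range(n_complexes):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        latent = np.sin(2.0 * math.pi * t * interval / period + phase)
        cid = f"C{c+1:03d}"
        for g in range(genes_per_complex):
            gid = f"{cid}_G{g+1:03d}"
            rows.append(latent + rng.normal(0.0, noise_sd, n_points))
            ids.append(gid)
            members.append({"complex_id": cid, "complex_name": f"synthetic complex {c+1}", "gene_id": gid})
    for b in range(n_background):
        ids.append(f"BG_{b+1:05d}")
        rows.append(rng.standard_normal(n_points))
    matrix = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.Index(ids, name="probeset_id"),
        columns=[f"t{i+1}" for i in range(n_points)],
    )
    membership = pd.DataFrame(members, columns=["complex_id", "complex_name", "gene_id"])
    return matrix, membership
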
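"""Seeded generators emulating the patterns the analysis is built to detect.

Three trace generators span the spectrum from random intermixing to
competition-driven segmentation:

* ``bernoulli`` — i.i.d. labels; the wild-type-chimera-like null where
  donor and host keratinocytes are finely intermingled.
* ``markov`` — a two-state chain with a persistence knob ``theta``; the
  stay probability in state ``s`` is ``theta + (1 - theta) * pi_s`` with
  ``pi_POS = p_pos``, which keeps the stationary composition at ``p_pos``
  for every ``theta`` and reduces exactly to Bernoulli at ``theta = 0``.
* ``encroachment`` — a minimal 1D lattice model of niche takeover: donor
  sites laterally convert adjacent host sites with probability
  ``adhesion_deficit`` (host never converts donor), coarsening an initially
  intermingled pattern into segmented clusters.  Its only claim is to
  produce segmented-versus-intermingled test patterns, not quantitative
  biology.

A mask renderer turns any trace into a label raster with a basal path for
end-to-end I/O testing, and a coverage-dataset generator draws per-animal
(chimerism %, coverage %) pairs from a logistic curve in log10-chimerism
with additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ValidationError
from .io import BasalTrace, LabelMask

Family = Literal["bernoulli", "markov", "encroachment"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of one trace generator run.

    ``p_pos`` is the target donor composition; ``theta`` the Markov
    persistence; ``adhesion_deficit`` the per-encounter probability that a
    donor site displaces an adjacent host site; ``donor_seed_fraction`` the
    initial donor occupancy and ``steps`` the number of lattice sweeps of
    the encroachment model.
    """

    family: Family
    length: int
    seed: int
    p_pos: float = 0.5
    theta: float | None = None
    adhesion_deficit: float | None = None
    donor_seed_fraction: float | None = None
    steps: int | None = None
    source_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"length must be >= 1, got {self.length}")
        if self.family not in ("bernoulli", "markov", "encroachment"):
            raise ValidationError(f"unknown family {self.family!r}")
        if not (0.0 <= self.p_pos <= 1.0):
            raise ValidationError(f"p_pos must be in [0, 1], got {self.p_pos}")
        if self.family == "markov":
            if self.theta is None or not (0.0 <= self.theta < 1.0):
                raise ValidationError(
                    f"markov family requires theta in [0, 1), got {self.theta}"
                )
        elif self.theta is not None:
            raise ValidationError("theta is only valid for the markov family")
        if self.family == "encroachment":
            if self.adhesion_deficit is None or not (0.0 <= self.adhesion_deficit <= 1.0):
                raise ValidationError(
                    "encroachment requires adhesion_deficit in [0, 1], got "
                    f"{self.adhesion_deficit}"
                )
            if self.donor_seed_fraction is None or not (0.0 < self.donor_seed_fraction < 1.0):
                raise ValidationError(
                    "encroachment requires donor_seed_fraction in (0, 1), got "
                    f"{self.donor_seed_fraction}"
                )
            if self.steps is None or self.steps < 0:
                raise ValidationError(
                    f"encroachment requires steps >= 0, got {self.steps}"
                )
        else:
            for name in ("adhesion_deficit", "donor_seed_fraction", "steps"):
                if getattr(self, name) is not None:
                    raise ValidationError(
                        f"{name} is only valid for the encroachment family"
                    )


# ---------------------------------------------------------------------------
# trace generators
# ---------------------------------------------------------------------------

def gen_bernoulli_trace(config: SyntheticConfig) -> BasalTrace:
    """I.i.d. labels with P(POS) = ``p_pos``; wild-type-chimera-like."""
    if config.family != "bernoulli":
        raise ValidationError(f"config family is {config.family!r}, not bernoulli")
    rng = np.random.default_rng(config.seed)
    labels = rng.random(config.length) < config.p_pos
    return BasalTrace(labels=labels, source_id=config.source_id)


def gen_markov_trace(config: SyntheticConfig) -> BasalTrace:
    """Two-state persistence chain with stationary composition ``p_pos``.

    The next label repeats the current one with probability ``theta`` and is
    otherwise redrawn from the stationary composition — i.e. the stay
    probability in state ``s`` is ``theta + (1 - theta) * pi_s``.  At
    ``theta = 0`` every draw is a fresh stationary draw, so the generator
    coincides with the Bernoulli one (and consumes the identical stream of
    uniforms, making the reduction exact per seed).
    """
    if config.family != "markov":
        raise ValidationError(f"config family is {config.family!r}, not markov")
    rng = np.random.default_rng(config.seed)
    u = rng.random(config.length)
    theta = float(config.theta)
    labels = np.empty(config.length, dtype=bool)
    labels[0] = u[0] < config.p_pos
    stay_draw = rng.random(config.length - 1) < theta if config.length > 1 else None
    for i in range(1, config.length):
        if stay_draw[i - 1]:
            labels[i] = labels[i - 1]
        else:
            labels[i] = u[i] < config.p_pos
    return BasalTrace(labels=labels, source_id=config.source_id)


def simulate_encroachment(
    config: SyntheticConfig,
) -> tuple[BasalTrace, np.ndarray]:
    """1D lattice niche-takeover simulation.

    Sites start i.i.d. donor with probability ``donor_seed_fraction``.  Each
    step visits sites in a fresh seeded random order; a visited donor site
    converts each adjacent host site with probability ``adhesion_deficit``.
    Host sites never convert donor sites, so donor occupancy is
    non-decreasing and, at deficit 1 with enough steps, absorbs the lattice
    whenever at least one donor site exists.

    Returns the final trace and the donor fraction after each step
    (element 0 is the initial fraction).
    """
    if config.family != "encroachment":
        raise ValidationError(
            f"config family is {config.family!r}, not encroachment"
        )
    rng = np.random.default_rng(config.seed)
    n = config.length
    donor = rng.random(n) < config.donor_seed_fraction
    fractions = [donor.mean()]
    deficit = float(config.adhesion_deficit)
    for _ in range(int(config.steps)):
        order = rng.permutation(n)
        attempts = rng.random((n, 2))
        for idx, site in enumerate(order):
            if not donor[site]:
                continue
            left = site - 1
            if left >= 0 and not donor[left] and attempts[idx, 0] < deficit:
                donor[left] = True
            right = site + 1
            if right < n and not donor[right] and attempts[idx, 1] < deficit:
                donor[right] = True
        fractions.append(donor.mean())
    trace = BasalTrace(labels=donor, source_id=config.source_id)
    return trace, np.asarray(fractions)


# ---------------------------------------------------------------------------
# mask rendering
# ---------------------------------------------------------------------------

def render_synthetic_mask(
    trace: BasalTrace, thickness: int = 5, margin: int = 2
) -> LabelMask:
    """Render a trace as a label raster with a flat basal path.

    The trace is laid along a horizontal band of the given pixel
    ``thickness`` over a background margin; the basal path runs along the
    bottom row of the band so re-extraction recovers the trace exactly.
    """
    if thickness < 1:
        raise ValidationError(f"thickness must be >= 1, got {thickness}")
    n = len(trace)
    pixels = np.zeros((margin + thickness + margin, n), dtype=np.uint8)
    band = np.where(trace.labels, 1, 2).astype(np.uint8)
    pixels[margin:margin + thickness, :] = band[None, :]
    basal_row = margin + thickness - 1
    return LabelMask(
        pixels=pixels,
        basal_path=[(basal_row, c) for c in range(n)],
        source_id=trace.source_id,
    )


# ---------------------------------------------------------------------------
# coverage datasets
# ---------------------------------------------------------------------------

@dataclass
class CoverageTruth:
    """Ground truth for synthetic chimerism-coverage datasets.

    Defaults mirror the analysis's reference condition: half-coverage at
    1.6% global chimerism on a logistic curve in log10-chimerism, with
    5-percentage-point observation noise over 40 animals spanning 0.1-100%
    chimerism.
    """

    c50: float = 1.6
    slope: float = 2.0
    noise_sd: float = 5.0
    n_animals: int = 40
    chimerism_range: tuple[float, float] = (0.1, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c50 <= 0:
            raise ValidationError(f"c50 must be positive, got {self.c50}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.chimerism_range
        if not (0 < lo < hi):
            raise ValidationError(
                f"chimerism_range must be positive and ordered, got {self.chimerism_range}"
            )
        if self.n_animals < 3:
            raise ValidationError(f"need n_animals >= 3, got {self.n_animals}")

    def expected_coverage(self, chimerism_pct) -> np.ndarray:
        z = self.slope * (np.log10(chimerism_pct) - np.log10(self.c50))
        return 100.0 / (1.0 + np.exp(-z))


def gen_coverage_dataset(truth: CoverageTruth) -> "list":
    """Draw per-animal (chimerism %, coverage %) pairs from the truth curve.

    Chimerism values are log-uniform over ``chimerism_range``; observed
    coverage is the logistic expectation plus Gaussian noise, clamped to
    [0, 100].
    """
    from .coverage import CoverageRecord

    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.chimerism_range
    chimerism = 10 ** rng.uniform(np.log10(lo), np.log10(hi), truth.n_animals)
    expected = truth.expected_coverage(chimerism)
    observed = np.clip(
        expected + rng.normal(0.0, truth.noise_sd, truth.n_animals), 0.0, 100.0
    )
    return [
        CoverageRecord(
            animal_id=f"animal{i:03d}",
            chimerism_pct=float(c),
            coverage_pct=float(v),
        )
        for i, (c, v) in enumerate(zip(chimerism, observed))
    ]
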
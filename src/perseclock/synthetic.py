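"""Synthetic methylation cohorts with known age-dependent CpG signal.

Real methylation cohorts have a minority of CpG loci whose beta value drifts
monotonically (and saturates) with age, buried in a large majority of
age-independent loci.  The generator emulates exactly that: an informative
locus j follows ``beta = inv_logit(a_j + b_j * z(age)) + noise`` (z =
standardized age), a noise locus draws from a Beta distribution around a
random per-locus baseline, everything is clamped to [0, 1], and tissue /
platform / dataset labels are attached so per-group reports can be
exercised.  The ground truth (which loci and channels are informative, and
their slopes) is returned alongside, which is what the attention-separation
and parameter-recovery experiments score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .meth_io import BetaMatrix
from .model import ClockConfig

TISSUES = ("whole blood", "saliva", "brain", "buccal",
           "liver", "muscle", "skin", "breast")
PLATFORMS = ("27K", "450K", "850K")
#: Beta-distribution concentration of age-independent loci (sd ~0.06 at beta 0.5)
NOISE_LOCUS_CONCENTRATION = 50.0


@dataclass
class SyntheticSpec:
    """Cohort recipe.  Defaults are the package's standard test cohort:

    432 loci in a 3 x 6 x 24 block geometry, 40 informative loci, 2,000
    samples, ages uniform on [0, 100] years, logit-scale age slope magnitude
    in [effect_scale/2, effect_scale] with random sign, and beta-value
    observation noise of sd 0.03.
    """

    n_samples: int = 2000
    n_loci: int = 432
    n_informative: int = 40
    age_low: float = 0.0
    age_high: float = 100.0
    effect_scale: float = 2.0
    noise_sd: float = 0.03
    missing_fraction: float = 0.0
    seed: int = 0
    trajectory: str = "logistic"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_loci < 1:
            raise ValueError("n_samples and n_loci must be positive")
        if not 0 <= self.n_informative <= self.n_loci:
            raise ValueError("n_informative must be in [0, n_loci]")
        if not self.age_low < self.age_high:
            raise ValueError("need age_low < age_high")
        if self.effect_scale <= 0 or self.noise_sd < 0:
            raise ValueError("effect_scale must be positive, noise_sd non-negative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.trajectory not in ("logistic", "linear"):
            raise ValueError("trajectory must be 'logistic' or 'linear'")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    informative_locus_ids: list[str]
    intercepts: np.ndarray
    slopes: np.ndarray
    informative_channels: np.ndarray = field(default=None)  # type: ignore[assignment]


def generate_cohort(spec: SyntheticSpec, cfg: ClockConfig | None = None
                    ) -> tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate (BetaMatrix, metadata table, truth), reproducibly from spec.seed."""
    cfg = cfg or ClockConfig(channels=None)
    channels = cfg.resolve_channels(spec.n_loci)  # hard error if indivisible
    rng = np.random.default_rng(spec.seed)

    ages = rng.uniform(spec.age_low, spec.age_high, size=spec.n_samples)
    # standardize by the theoretical moments of Uniform(low, high) so that
    # effect_scale means the same thing for any age window
    z = (ages - (spec.age_low + spec.age_high) / 2.0) \
        / ((spec.age_high - spec.age_low) / np.sqrt(12.0))

    locus_ids = [f"cg{j:08d}" for j in range(spec.n_loci)]
    informative = np.sort(rng.choice(spec.n_loci, size=spec.n_informative,
                                     replace=False))
    intercepts = rng.uniform(-1.0, 1.0, size=spec.n_informative)
    slopes = rng.uniform(spec.effect_scale / 2.0, spec.effect_scale,
                         size=spec.n_informative)
    slopes *= rng.choice([-1.0, 1.0], size=spec.n_informative)

    values = np.empty((spec.n_samples, spec.n_loci))
    noise_mask = np.ones(spec.n_loci, dtype=bool)
    noise_mask[informative] = False
    n_noise = int(noise_mask.sum())
    if n_noise:
        base = rng.uniform(0.1, 0.9, size=n_noise)
        kappa = NOISE_LOCUS_CONCENTRATION
        values[:, noise_mask] = rng.beta(base * kappa, (1.0 - base) * kappa,
                                         size=(spec.n_samples, n_noise))
    if spec.n_informative:
        lin = intercepts[None, :] + slopes[None, :] * z[:, None]
        if spec.trajectory == "logistic":
            signal = expit(lin)
        else:
            signal = 0.5 + 0.25 * lin  # linear drift around mid-methylation
        values[:, informative] = signal
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    np.clip(values, 0.0, 1.0, out=values)

    sample_ids = [f"S{i:05d}" for i in range(spec.n_samples)]
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "age": ages,
        "tissue": [TISSUES[i % len(TISSUES)] for i in range(spec.n_samples)],
        "platform": [PLATFORMS[i % len(PLATFORMS)] for i in range(spec.n_samples)],
        "dataset_id": [f"SYN{i % 5 + 1}" for i in range(spec.n_samples)],
    })

    truth = SyntheticTruth(
        informative_locus_ids=[locus_ids[j] for j in informative],
        intercepts=intercepts,
        slopes=slopes,
        informative_channels=np.unique(informative % channels),
    )
    bm = BetaMatrix(sample_ids, locus_ids, values,
                    np.zeros(values.shape, dtype=bool))
    if spec.missing_fraction > 0:
        bm = inject_missingness(bm, spec.missing_fraction, spec.seed + 1)
    return bm, meta, truth


def inject_missingness(bm: BetaMatrix, fraction: float, seed=0) -> BetaMatrix:
    """Mask exactly round(fraction * n_entries) currently observed cells at random.

    The true values stay in ``values`` under the mask, so imputation accuracy
    can be scored against them.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    out = bm.copy()
    k = int(round(fraction * bm.values.size))
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    flat_candidates = np.flatnonzero(~bm.mask.ravel())
    if k > flat_candidates.size:
        raise ValueError("not enough observed entries to mask")
    chosen = rng.choice(flat_candidates, size=k, replace=False)
    flat = out.mask.ravel()
    flat[chosen] = True
    out.mask = flat.reshape(bm.mask.shape)
    return out
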
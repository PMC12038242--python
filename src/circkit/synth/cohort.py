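"""Two-class negative-binomial cohort count matrices with planted signal.

Stands in for patient cohorts profiled by RNA-seq: a features x samples
integer count matrix where a chosen subset of features carries a
class-dependent fold change, everything else is exchangeable noise.  The
identity of the informative features is recorded so feature-selection and
classifier recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer counts (features x samples) plus per-sample design metadata."""

    counts: pd.DataFrame
    design: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"design does not cover samples: {sorted(missing)}")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion (var = mu + a*mu^2)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort_matrix(
    n_features: int,
    n_per_class: int | tuple[int, int],
    n_informative: int,
    effect_log2fc: float | np.ndarray = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    *,
    base_mean_log2_range: tuple[float, float] = (5.0, 9.0),
    class_labels: tuple[str, str] = ("healthy", "disease"),
) -> CountMatrix:
    """Simulate a two-class cohort with ``n_informative`` planted features.

    ``effect_log2fc`` is the class-B over class-A log2 fold change; a
    scalar applies to every informative feature, a vector (length
    ``n_informative``) allows mixed directions and magnitudes.  Base means
    are log-uniform over ``base_mean_log2_range`` (defaults span counts of
    roughly 32-512).
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    if isinstance(n_per_class, int):
        n_a = n_b = n_per_class
    else:
        n_a, n_b = n_per_class
    rng = np.random.default_rng(seed)
    effects = np.zeros(n_features)
    eff = np.asarray(effect_log2fc, dtype=float)
    if eff.ndim == 0:
        effects[:n_informative] = float(eff)
    else:
        if eff.shape != (n_informative,):
            raise ValueError("effect vector length must equal n_informative")
        effects[:n_informative] = eff

    base = 2.0 ** rng.uniform(*base_mean_log2_range, size=n_features)
    mean_a = base
    mean_b = base * 2.0**effects

    counts_a = _nb_sample(rng, np.repeat(mean_a[:, None], n_a, axis=1), dispersion)
    counts_b = _nb_sample(rng, np.repeat(mean_b[:, None], n_b, axis=1), dispersion)

    features = [f"feat_{i + 1:05d}" for i in range(n_features)]
    samples = [f"{class_labels[0]}_{j + 1:03d}" for j in range(n_a)] + [
        f"{class_labels[1]}_{j + 1:03d}" for j in range(n_b)
    ]
    counts = pd.DataFrame(
        np.hstack([counts_a, counts_b]), index=features, columns=samples, dtype=int
    )
    design = pd.DataFrame(
        {
            "class": [class_labels[0]] * n_a + [class_labels[1]] * n_b,
            "replicate": list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
        },
        index=samples,
    )
    truth = {
        "informative": features[:n_informative],
        "effect_log2fc": effects[:n_informative].copy(),
        "dispersion": dispersion,
    }
    return CountMatrix(counts=counts, design=design, truth=truth)
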
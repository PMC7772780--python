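"""Power-law normalization of CAGE tag counts.

CAGE tag-count distributions are heavy-tailed: the reverse cumulative
count revcum(x) = #{positions with count >= x} is close to a power law
c * x^(-alpha) over a wide range.  Libraries of different depths and
slopes are made comparable by fitting each sample's power law and
rank-matching its counts onto a shared reference law with slope
``alpha_ref`` (default 1.14) and implied total tag count ``total_T``
(default 1e7), reported in tags per million (tpm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import CTSSTable

X_MAX = 10**6  # upper limit of the discrete reference-law summation


class DegenerateFitError(ValueError):
    """Raised when a sample has too few distinct counts to fit a slope."""


@dataclass(frozen=True)
class NormalizationConfig:
    alpha_ref: float = 1.14
    total_T: float = 1e7
    fit_min_count: float = 2
    fit_min_revcum: int = 100
    output_units: str = "tags per million"

    def __post_init__(self) -> None:
        if self.alpha_ref <= 0 or self.total_T <= 0:
            raise ValueError("alpha_ref and total_T must be positive")


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted revcum(x) ~ c_s * x^(-alpha_s) for one sample."""

    alpha_s: float
    c_s: float
    fit_range: tuple[float, float]
    n_points: int


def reverse_cumulative(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct values (ascending) and the count of entries >= each value."""
    values = np.asarray(values)
    distinct = np.unique(values)
    # entries >= v = total - entries < v
    below = np.searchsorted(np.sort(values), distinct, side="left")
    revcum = len(values) - below
    return distinct, revcum


def fit_power_law_values(
    values: np.ndarray, fit_min_count: float = 2, fit_min_revcum: int = 100
) -> PowerLawFit:
    """OLS fit of log10 revcum on log10 value over distinct values >= fit_min_count.

    The extreme tail — distinct values backed by fewer than
    ``fit_min_revcum`` positions — has enormous variance on the log scale
    and flattens an unweighted fit, so it is excluded whenever at least
    two better-supported points remain; small samples fall back to the
    full eligible range.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateFitError("empty sample")
    distinct, revcum = reverse_cumulative(values)
    mask = distinct >= fit_min_count
    trimmed = mask & (revcum >= fit_min_revcum)
    if trimmed.sum() >= 2:
        mask = trimmed
    x = distinct[mask]
    y = revcum[mask]
    if len(x) < 2:
        raise DegenerateFitError(
            f"need >= 2 distinct values >= {fit_min_count}, found {len(x)}"
        )
    res = stats.linregress(np.log10(x), np.log10(y))
    alpha_s = -res.slope
    c_s = 10.0**res.intercept
    if not (alpha_s > 0 and np.isfinite(c_s)):
        raise DegenerateFitError(f"non-physical fit: alpha={alpha_s}, c={c_s}")
    return PowerLawFit(
        alpha_s=float(alpha_s),
        c_s=float(c_s),
        fit_range=(float(x[0]), float(x[-1])),
        n_points=int(len(x)),
    )


def fit_power_law(ctss: CTSSTable, config: NormalizationConfig = NormalizationConfig()) -> PowerLawFit:
    """Fit the sample's raw-count reverse-cumulative power law."""
    return fit_power_law_values(
        ctss.data["raw_count"].to_numpy(),
        fit_min_count=config.fit_min_count,
        fit_min_revcum=config.fit_min_revcum,
    )


def reference_intercept(config: NormalizationConfig = NormalizationConfig()) -> float:
    """Intercept c_ref of the reference law revcum(x) = c_ref * x^(-alpha_ref).

    Chosen so that the law's implied total tag count over integer counts
    1..X_MAX equals total_T: the total is sum_x revcum(x) (each position of
    count k contributes to revcum at x = 1..k).
    """
    x = np.arange(1, X_MAX + 1, dtype=float)
    partial_sum = np.sum(x**-config.alpha_ref)
    return config.total_T / partial_sum


def normalized_counts(
    raw_counts: np.ndarray,
    fit: PowerLawFit,
    config: NormalizationConfig = NormalizationConfig(),
) -> np.ndarray:
    """Map raw counts onto the reference law's count scale.

    A count x at empirical rank revcum_fit(x) = c_s x^(-alpha_s) is sent to
    the reference count z with the same rank: c_ref z^(-alpha_ref) =
    c_s x^(-alpha_s), i.e. z = (c_s x^(-alpha_s) / c_ref)^(-1/alpha_ref).
    The map is strictly increasing in x.
    """
    c_ref = reference_intercept(config)
    x = np.asarray(raw_counts, dtype=float)
    return (fit.c_s * x**-fit.alpha_s / c_ref) ** (-1.0 / config.alpha_ref)


def inverse_normalized_counts(
    ref_counts: np.ndarray,
    fit: PowerLawFit,
    config: NormalizationConfig = NormalizationConfig(),
) -> np.ndarray:
    """Inverse of :func:`normalized_counts`: reference count -> raw count."""
    c_ref = reference_intercept(config)
    z = np.asarray(ref_counts, dtype=float)
    return (c_ref * z**-config.alpha_ref / fit.c_s) ** (-1.0 / fit.alpha_s)


def normalize_to_reference(
    ctss: CTSSTable,
    fit: PowerLawFit | None = None,
    config: NormalizationConfig = NormalizationConfig(),
) -> CTSSTable:
    """Return a copy of the table with norm_tpm filled in.

    norm_tpm = z(raw_count) * 1e6 / total_T, so a position carrying the
    reference law's average share of total_T tags per million reads as tpm.
    """
    if fit is None:
        fit = fit_power_law(ctss, config)
    df = ctss.data.copy()
    df["norm_tpm"] = (
        normalized_counts(df["raw_count"].to_numpy(), fit, config)
        * 1e6
        / config.total_T
    )
    return CTSSTable(sample_id=ctss.sample_id, data=df)


def sample_discrete_power_law(
    n: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n integer counts with P(X >= x) = x^(-alpha) for integer x >= 1.

    Inverse-CDF construction: X = floor(U^(-1/alpha)) gives exactly that
    reverse-cumulative law.  Used by the synthetic generator and tests.
    """
    u = rng.random(n)
    x = np.floor(u ** (-1.0 / alpha))
    # protect against overflow from u ~ 0
    return np.minimum(x, 1e12).astype(np.int64)
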
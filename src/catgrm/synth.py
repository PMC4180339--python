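"""GRM-consistent synthetic respondents with covariates and optional DIF.

The generator draws a latent trait theta from a Gaussian mixture that is
right-heavy with a near-floor clinical subgroup (so roughly one in five
simulated respondents scores zero on every item), then samples ordinal
responses from the bank's category distributions at each person's theta.
Covariates are drawn independently of theta by default, so group
membership carries no information about responses unless uniform DIF is
explicitly injected as a threshold shift on one item for one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import COVARIATE_LEVELS, ItemBank, ResponseMatrix

__all__ = ["DEFAULT_THETA_MIXTURE", "CohortSpec", "Cohort", "sample_thetas",
           "simulate_responses", "generate_cohort"]

#: default clinical mixture: 20% near-floor component + 80% right-shifted bulk
DEFAULT_THETA_MIXTURE: tuple[tuple[float, float, float], ...] = (
    (0.2, -2.2, 0.4),
    (0.8, 0.6, 1.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort; the seed fixes everything."""

    n_persons: int
    bank: ItemBank
    seed: int
    theta_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_THETA_MIXTURE
    covariate_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    dif_injection: dict | None = None  # {item_id, group_covariate, focal_level, beta_shift}

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        mix = np.asarray(self.theta_mixture, dtype=float)
        if mix.ndim != 2 or mix.shape[1] != 3:
            raise ValueError("theta_mixture must be a list of (weight, mean, sd)")
        if not np.isclose(mix[:, 0].sum(), 1.0):
            raise ValueError(f"mixture weights must sum to 1, got {mix[:, 0].sum()}")
        if np.any(mix[:, 0] < 0) or np.any(mix[:, 2] <= 0):
            raise ValueError("mixture weights must be >= 0 and sds > 0")
        if self.dif_injection is not None:
            need = {"item_id", "group_covariate", "beta_shift"}
            if not need <= set(self.dif_injection):
                raise ValueError(f"dif_injection needs keys {sorted(need)}")
            item_id = self.dif_injection["item_id"]
            if not any(it.id == item_id for it in self.bank):
                raise ValueError(f"dif_injection targets item {item_id} not in bank")


@dataclass
class Cohort:
    matrix: ResponseMatrix
    true_thetas: np.ndarray

    @property
    def covariates(self) -> pd.DataFrame | None:
        return self.matrix.covariates


def sample_thetas(spec: CohortSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n_persons thetas from the spec's Gaussian mixture."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mix = np.asarray(spec.theta_mixture, dtype=float)
    comp = rng.choice(len(mix), size=spec.n_persons, p=mix[:, 0])
    return rng.normal(mix[comp, 1], mix[comp, 2])


def simulate_responses(
    bank: ItemBank,
    thetas: np.ndarray,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ResponseMatrix:
    """Sample one ordinal response per person-item cell from the GRM.

    Uses one uniform draw per cell against the boundary curves: the
    response is the number of boundary probabilities exceeding the draw,
    which reproduces P(X >= k) = P*_k exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    thetas = np.asarray(thetas, dtype=float)
    n, K = thetas.shape[0], len(bank)
    from scipy.special import expit

    pstar = expit(
        bank.alphas[None, :, None] * (thetas[:, None, None] - bank.beta_matrix[None, :, :])
    )  # (n, K, m)
    u = rng.random((n, K))
    responses = (u[:, :, None] < pstar).sum(axis=2)
    return ResponseMatrix(person_ids=np.arange(1, n + 1), responses=responses)


def _sample_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, levels in COVARIATE_LEVELS.items():
        probs = spec.covariate_probs.get(name)
        if probs is None:
            p = np.full(len(levels), 1.0 / len(levels))
            lv = list(levels)
        else:
            lv = list(probs)
            p = np.asarray([probs[level] for level in lv], dtype=float)
            if not np.isclose(p.sum(), 1.0):
                raise ValueError(f"covariate {name}: level probabilities must sum to 1")
        cols[name] = rng.choice(lv, size=spec.n_persons, p=p)
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full cohort draw: thetas, covariates, then GRM responses.

    Covariates are independent of theta, so there is no impact confound.
    With ``dif_injection`` set, the focal group's responses to the target
    item come from a bank whose thresholds for that item are shifted by
    ``beta_shift`` (uniform DIF: both thresholds move equally).
    """
    rng = np.random.default_rng(spec.seed)
    thetas = sample_thetas(spec, rng)
    covariates = _sample_covariates(spec, rng)
    matrix = simulate_responses(spec.bank, thetas, rng)

    if spec.dif_injection is not None:
        inj = spec.dif_injection
        cov = inj["group_covariate"]
        if cov not in covariates.columns:
            raise ValueError(f"dif_injection covariate {cov!r} unknown")
        focal_level = inj.get("focal_level", COVARIATE_LEVELS[cov][1])
        focal = (covariates[cov] == focal_level).to_numpy()
        item = spec.bank[inj["item_id"]]
        shifted_bank = spec.bank.replace_item(item.shifted(inj["beta_shift"]))
        # redraw only the focal group's target-item column under the shifted bank,
        # from an independent substream so the ambient cohort is untouched
        sub_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
        redraw = simulate_responses(shifted_bank, thetas[focal], sub_rng)
        responses = matrix.responses.copy()
        responses[focal, item.id - 1] = redraw.responses[:, item.id - 1]
        matrix = ResponseMatrix(matrix.person_ids, responses)

    matrix = ResponseMatrix(matrix.person_ids, matrix.responses, covariates)
    return Cohort(matrix=matrix, true_thetas=thetas)
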
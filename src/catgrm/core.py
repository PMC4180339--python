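"""Data model, validation and readers/writers for item banks and response matrices.

An :class:`ItemBank` holds ordered polytomous items under the graded
response model (GRM): each item has a discrimination ``alpha`` and a
strictly increasing vector of threshold parameters ``betas``.  A
:class:`ResponseMatrix` is the persons-by-items integer category matrix
(complete cases only) plus optional per-person categorical covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Item",
    "ItemBank",
    "ResponseMatrix",
    "PipelineConfig",
    "ValidationReport",
    "BankFormatError",
    "BankValidationError",
    "ResponseValidationError",
    "default_bank",
    "load_item_bank",
    "load_response_matrix",
    "write_response_matrix",
    "validate_dataset",
    "load_config",
]

#: covariate columns recognised in response CSV files, with their levels
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "age_band": ("18-49", "50-69"),
    "education": ("low", "high"),
    "mode": ("computer", "paper"),
}


class BankFormatError(ValueError):
    """Raised when an item-bank file is structurally malformed."""


class BankValidationError(ValueError):
    """Raised when item-bank contents violate GRM parameter constraints."""


class ResponseValidationError(ValueError):
    """Raised when a response matrix violates the complete-case contract."""


@dataclass(frozen=True)
class Item:
    """A single GRM item: discrimination ``alpha`` and ordered thresholds."""

    id: int
    label: str
    alpha: float
    betas: tuple[float, ...]

    @property
    def n_categories(self) -> int:
        return len(self.betas) + 1

    def validate(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise BankValidationError(
                f"item {self.id} ({self.label!r}): alpha must be positive, got {self.alpha}"
            )
        b = np.asarray(self.betas, dtype=float)
        if b.size < 1 or not np.all(np.isfinite(b)):
            raise BankValidationError(f"item {self.id}: betas must be finite and non-empty")
        if not np.all(np.diff(b) > 0):
            raise BankValidationError(
                f"item {self.id} ({self.label!r}): betas must be strictly increasing, got {self.betas}"
            )

    def shifted(self, delta: float) -> "Item":
        """Return a copy with every threshold moved by ``delta`` (uniform shift)."""
        return Item(self.id, self.label, self.alpha, tuple(b + delta for b in self.betas))


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of GRM items sharing one category count."""

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise BankValidationError("item bank is empty")
        for item in self.items:
            item.validate()
        ncats = {it.n_categories for it in self.items}
        if len(ncats) != 1:
            raise BankValidationError(f"items disagree on category count: {sorted(ncats)}")
        ids = [it.id for it in self.items]
        if ids != list(range(1, len(ids) + 1)):
            raise BankValidationError(f"item ids must be 1..{len(ids)} contiguous, got {ids}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self.items)

    def __getitem__(self, item_id: int) -> Item:
        """Look up an item by its 1-based id."""
        if not 1 <= item_id <= len(self.items):
            raise KeyError(f"no item with id {item_id}")
        return self.items[item_id - 1]

    @property
    def n_categories(self) -> int:
        return self.items[0].n_categories

    @property
    def max_category(self) -> int:
        return self.n_categories - 1

    @property
    def alphas(self) -> np.ndarray:
        return np.array([it.alpha for it in self.items])

    @property
    def beta_matrix(self) -> np.ndarray:
        """(n_items, m) threshold matrix."""
        return np.array([it.betas for it in self.items])

    def replace_item(self, item: Item) -> "ItemBank":
        items = list(self.items)
        items[item.id - 1] = item
        return ItemBank(tuple(items))

    def to_frame(self) -> pd.DataFrame:
        m = self.n_categories - 1
        rows = [
            {"id": it.id, "label": it.label, "alpha": it.alpha,
             **{f"beta{k + 1}": it.betas[k] for k in range(m)}}
            for it in self.items
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        payload = [
            {"id": it.id, "label": it.label, "alpha": it.alpha, "betas": list(it.betas)}
            for it in self.items
        ]
        Path(path).write_text(json.dumps(payload, indent=2))


def _bank_from_frame(df: pd.DataFrame) -> ItemBank:
    required = {"id", "label", "alpha"}
    missing = required - set(df.columns)
    if missing:
        raise BankFormatError(f"item bank missing required columns: {sorted(missing)}")
    beta_cols = sorted(
        (c for c in df.columns if c.startswith("beta") and c[4:].isdigit()),
        key=lambda c: int(c[4:]),
    )
    if not beta_cols:
        raise BankFormatError("item bank has no beta1..betam columns")
    expected = [f"beta{k}" for k in range(1, len(beta_cols) + 1)]
    if beta_cols != expected:
        raise BankFormatError(f"beta columns must be contiguous beta1..betam, got {beta_cols}")
    items = []
    for _, row in df.iterrows():
        items.append(
            Item(
                id=int(row["id"]),
                label=str(row["label"]),
                alpha=float(row["alpha"]),
                betas=tuple(float(row[c]) for c in beta_cols),
            )
        )
    return ItemBank(tuple(items))


def load_item_bank(path: str | Path) -> ItemBank:
    """Read an item bank from CSV (columns id,label,alpha,beta1..betam) or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        items = tuple(
            Item(int(d["id"]), str(d["label"]), float(d["alpha"]), tuple(map(float, d["betas"])))
            for d in payload
        )
        return ItemBank(items)
    return _bank_from_frame(pd.read_csv(path))


def default_bank() -> ItemBank:
    """The 19-item BSS-NL calibration shipped with the package (3 categories)."""
    with resources.files("catgrm.data").joinpath("bss_nl_bank.csv").open("r") as fh:
        return _bank_from_frame(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# response matrices


@dataclass
class ResponseMatrix:
    """Persons x items integer categories plus optional categorical covariates."""

    person_ids: np.ndarray
    responses: np.ndarray  # (n_persons, n_items) int
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.person_ids = np.asarray(self.person_ids)
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.ndim != 2:
            raise ResponseValidationError("responses must be a 2-D matrix")
        if len(self.person_ids) != self.responses.shape[0]:
            raise ResponseValidationError("person_ids length does not match response rows")
        if len(np.unique(self.person_ids)) != len(self.person_ids):
            raise ResponseValidationError("person_ids must be unique")
        if self.covariates is not None and len(self.covariates) != self.responses.shape[0]:
            raise ResponseValidationError("covariate rows do not match response rows")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def total_scores(self) -> np.ndarray:
        return self.responses.sum(axis=1)

    def check_against_bank(self, bank: ItemBank) -> None:
        if self.n_items != len(bank):
            raise ResponseValidationError(
                f"matrix has {self.n_items} item columns but bank has {len(bank)} items"
            )
        bad = (self.responses < 0) | (self.responses > bank.max_category)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ResponseValidationError(
                f"response {self.responses[i, j]} out of range 0..{bank.max_category} "
                f"at person {self.person_ids[i]!r}, item {j + 1}"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.responses, columns=[f"item_{j + 1}" for j in range(self.n_items)]
        )
        df.insert(0, "person_id", self.person_ids)
        if self.covariates is not None:
            for col in self.covariates.columns:
                df[col] = self.covariates[col].to_numpy()
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def write_response_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    matrix.write_csv(path)


def load_response_matrix(path: str | Path, bank: ItemBank | None = None) -> ResponseMatrix:
    """Read a response CSV (person_id, item_1..item_K, optional covariates).

    Rows with any missing item response are rejected: all analyses operate
    on complete cases only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise ResponseValidationError("response CSV must have a person_id column")
    item_cols = sorted(
        (c for c in df.columns if c.startswith("item_") and c[5:].isdigit()),
        key=lambda c: int(c[5:]),
    )
    if not item_cols:
        raise ResponseValidationError("response CSV has no item_1..item_K columns")
    expected = [f"item_{k}" for k in range(1, len(item_cols) + 1)]
    if item_cols != expected:
        raise ResponseValidationError(f"item columns must be contiguous item_1..item_K, got {item_cols}")

    block = df[item_cols]
    if block.isna().any().any():
        r, c = next(zip(*np.where(block.isna().to_numpy())))
        raise ResponseValidationError(
            f"missing response at row {r}, column {item_cols[c]}: complete cases only"
        )
    values = block.to_numpy()
    if not np.all(values == np.floor(values)):
        raise ResponseValidationError("non-integer response categories found")
    responses = values.astype(int)

    cov_cols = [c for c in COVARIATE_LEVELS if c in df.columns]
    covariates = None
    if cov_cols:
        covariates = df[cov_cols].copy()
        for col in cov_cols:
            covariates[col] = covariates[col].astype(str).str.strip().str.lower()

    matrix = ResponseMatrix(
        person_ids=df["person_id"].to_numpy(), responses=responses, covariates=covariates
    )
    if bank is not None:
        matrix.check_against_bank(bank)
    return matrix


# ---------------------------------------------------------------------------
# dataset validation report


@dataclass
class ValidationReport:
    """Per-item category counts with empty-category flags (pre-fit screening)."""

    category_counts: pd.DataFrame  # items x categories
    empty_categories: list[tuple[int, int]]  # (item_id, category)

    @property
    def ok(self) -> bool:
        return not self.empty_categories

    def flagged_items(self) -> list[int]:
        return sorted({item for item, _ in self.empty_categories})


def validate_dataset(matrix: ResponseMatrix, bank: ItemBank) -> ValidationReport:
    """Tabulate category counts per item and flag empty categories.

    Items with an unobserved category cannot be calibrated without
    collapsing, so they are surfaced here before any GRM fit.
    """
    if matrix.n_persons == 0:
        raise ResponseValidationError("empty dataset: no persons")
    matrix.check_against_bank(bank)
    m = bank.max_category
    counts = np.zeros((len(bank), m + 1), dtype=int)
    for j in range(len(bank)):
        counts[j] = np.bincount(matrix.responses[:, j], minlength=m + 1)
    table = pd.DataFrame(
        counts,
        index=pd.Index(range(1, len(bank) + 1), name="item"),
        columns=[f"n{k}" for k in range(m + 1)],
    )
    empty = [
        (item_id, k)
        for item_id, row in zip(table.index, counts)
        for k, n in enumerate(row)
        if n == 0
    ]
    return ValidationReport(category_counts=table, empty_categories=empty)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Seeded configuration for the full five-step pipeline.

    Every screening threshold has a named key defaulting to its
    conventional printed value; all are overridable from YAML.
    """

    seed: int
    estimator: str = "EAP"
    quadrature_nodes: int = 41
    theta_grid_range: tuple[float, float] = (-4.5, 4.5)
    theta_grid_nodes: int = 61
    dif_alpha: float = 0.01
    cronbach_alpha_floor: float = 0.8
    pca_prop_var_min: float = 0.20
    pca_ratio_min: float = 4.0
    residual_corr_flag: float = 0.2
    scalability_flag: float = 0.3
    mcfadden_negligible: float = 0.13
    mcfadden_moderate: float = 0.26
    cat: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.estimator not in ("EAP", "MLE"):
            raise ValueError(f"estimator must be EAP or MLE, got {self.estimator!r}")
        for name in ("dif_alpha", "pca_prop_var_min", "pca_ratio_min",
                     "residual_corr_flag", "scalability_flag",
                     "mcfadden_negligible", "mcfadden_moderate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "theta_grid_range" in raw:
        raw["theta_grid_range"] = tuple(raw["theta_grid_range"])
    return PipelineConfig(**raw)
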
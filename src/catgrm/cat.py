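"""Post-hoc computer-adaptive-testing simulation with classification stopping.

Items are selected by maximum Fisher information at the current trait
estimate and "administered" by replaying each person's recorded full-test
response.  Testing stops once the confidence interval around the trait
estimate falls entirely on one side of the risk cut-off (subject to a
minimum item count), at the item cap, or when the bank is exhausted.
Classification is elevated risk when the final estimate exceeds the
cut-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ItemBank, ResponseMatrix
from .grm import ThetaEstimate, estimate_theta, eap_scores, item_information

__all__ = [
    "CATConfig",
    "CATResult",
    "SimulationSummary",
    "select_next_item",
    "check_stopping",
    "run_cat_post_hoc",
    "simulate_cohort_cat",
    "compare_stopping_rules",
    "export_decision_tree",
    "tree_to_dot",
]


@dataclass(frozen=True)
class CATConfig:
    """Stopping and selection rules for one CAT run."""

    entry_theta: float = 0.0
    estimator: str = "EAP"
    cutoff_theta: float = -1.0
    confidence: float = 0.99
    min_items: int = 3
    max_items: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie strictly between 0 and 1")
        if not 1 <= self.min_items <= self.max_items:
            raise ValueError("need 1 <= min_items <= max_items")
        if self.estimator not in ("EAP", "MLE"):
            raise ValueError(f"estimator must be EAP or MLE, got {self.estimator!r}")

    @property
    def z(self) -> float:
        """Two-sided normal quantile for the configured confidence (2.5758 at 99%)."""
        return float(stats.norm.ppf(0.5 + self.confidence / 2.0))


@dataclass
class CATResult:
    administered: list[int]
    responses: list[int]
    theta_trajectory: list[tuple[float, float]]  # (theta_hat, se) after each item
    stop_reason: str  # classified | max_items | bank_exhausted
    classification: str  # elevated | low

    @property
    def n_items(self) -> int:
        return len(self.administered)

    @property
    def final_theta(self) -> float:
        return self.theta_trajectory[-1][0]


def select_next_item(bank: ItemBank, administered, theta_current: float) -> int:
    """Id of the unadministered item with maximum information at theta_current.

    Ties break to the lowest item id (deterministic replay).
    """
    used = set(administered)
    best_id, best_info = None, -np.inf
    for item in bank:
        if item.id in used:
            continue
        info = float(item_information(item, theta_current))
        if info > best_info + 1e-12:
            best_id, best_info = item.id, info
    if best_id is None:
        raise ValueError("no unadministered items remain; check stopping first")
    return best_id


def check_stopping(
    estimate: ThetaEstimate,
    config: CATConfig,
    n_administered: int,
    n_remaining: int,
) -> tuple[bool, str | None]:
    """Classification stopping rule on the normal-approximation CI.

    Stop "classified" when theta_hat +- z*se lies entirely on one side of
    the cut-off and at least min_items were given; stop "max_items" at
    the cap; stop "bank_exhausted" when no items remain.
    """
    lo = estimate.theta_hat - config.z * estimate.se
    hi = estimate.theta_hat + config.z * estimate.se
    if n_administered >= config.min_items and (lo > config.cutoff_theta or hi < config.cutoff_theta):
        return True, "classified"
    if n_administered >= config.max_items:
        return True, "max_items"
    if n_remaining == 0:
        return True, "bank_exhausted"
    return False, None


def run_cat_post_hoc(
    bank: ItemBank, full_responses: np.ndarray, config: CATConfig
) -> CATResult:
    """Replay one person's complete response vector through the CAT loop."""
    full_responses = np.asarray(full_responses, dtype=int)
    if full_responses.shape != (len(bank),):
        raise ValueError(f"expected a complete vector of {len(bank)} responses")
    if full_responses.min() < 0 or full_responses.max() > bank.max_category:
        raise ValueError("responses out of category range")

    administered: list[int] = []
    responses: dict[int, int] = {}
    trajectory: list[tuple[float, float]] = []
    theta = config.entry_theta
    max_items = min(config.max_items, len(bank))

    while True:
        next_id = select_next_item(bank, administered, theta)
        administered.append(next_id)
        responses[next_id] = int(full_responses[next_id - 1])
        est = estimate_theta(bank, responses, method=config.estimator)
        if config.estimator == "MLE" and est.boundary:
            est = estimate_theta(bank, responses, method="EAP")
        theta = est.theta_hat
        trajectory.append((est.theta_hat, est.se))
        stop, reason = check_stopping(
            est, config, len(administered), len(bank) - len(administered)
        )
        if len(administered) >= max_items and not stop:
            stop, reason = True, "max_items"
        if stop:
            break

    classification = "elevated" if theta > config.cutoff_theta else "low"
    return CATResult(
        administered=administered,
        responses=[responses[i] for i in administered],
        theta_trajectory=trajectory,
        stop_reason=reason or "max_items",
        classification=classification,
    )


@dataclass
class SimulationSummary:
    n_persons: int
    mean_items: float
    sd_items: float
    n_low: int
    n_elevated: int
    agreement_with_full_test: float
    results: list[CATResult] = field(default_factory=list)
    config: CATConfig | None = None

    def to_row(self) -> dict:
        return {
            "min_items": self.config.min_items if self.config else None,
            "max_items": self.config.max_items if self.config else None,
            "mean_items": self.mean_items,
            "sd_items": self.sd_items,
            "n_low": self.n_low,
            "n_elevated": self.n_elevated,
            "agreement_with_full_test": self.agreement_with_full_test,
        }


def full_test_classification(bank: ItemBank, matrix: ResponseMatrix, cutoff: float = -1.0) -> np.ndarray:
    """Reference classification: EAP over all items against the cut-off."""
    theta = eap_scores(bank, matrix)["theta_hat"].to_numpy()
    return theta > cutoff


def simulate_cohort_cat(
    bank: ItemBank, matrix: ResponseMatrix, config: CATConfig, keep_results: bool = True
) -> SimulationSummary:
    """Run the post-hoc CAT for every person and summarise.

    Agreement compares the CAT classification with the full-test EAP
    classification at the same cut-off.
    """
    matrix.check_against_bank(bank)
    reference = full_test_classification(bank, matrix, config.cutoff_theta)
    results = []
    n_items = np.empty(matrix.n_persons)
    elevated = np.empty(matrix.n_persons, dtype=bool)
    for i in range(matrix.n_persons):
        res = run_cat_post_hoc(bank, matrix.responses[i], config)
        n_items[i] = res.n_items
        elevated[i] = res.classification == "elevated"
        if keep_results:
            results.append(res)
    agreement = float((elevated == reference).mean())
    return SimulationSummary(
        n_persons=matrix.n_persons,
        mean_items=float(n_items.mean()),
        sd_items=float(n_items.std(ddof=1)) if matrix.n_persons > 1 else 0.0,
        n_low=int((~elevated).sum()),
        n_elevated=int(elevated.sum()),
        agreement_with_full_test=agreement,
        results=results,
        config=config,
    )


def compare_stopping_rules(
    bank: ItemBank,
    matrix: ResponseMatrix,
    base: CATConfig | None = None,
    rules: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Stopping-rule comparison table: full administration vs CI-rule variants.

    Default rules mirror the printed comparison: (19,19) full test,
    (3,19) CI rule, and (3,6) CI rule with an item cap.
    """
    base = base or CATConfig()
    K = len(bank)
    rules = rules or [(K, K), (3, K), (3, 6)]
    rows = []
    for lo, hi in rules:
        cfg = CATConfig(
            entry_theta=base.entry_theta, estimator=base.estimator,
            cutoff_theta=base.cutoff_theta, confidence=base.confidence,
            min_items=lo, max_items=hi,
        )
        summary = simulate_cohort_cat(bank, matrix, cfg, keep_results=False)
        rows.append(summary.to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decision-tree export


def export_decision_tree(bank: ItemBank, config: CATConfig, max_depth: int) -> dict:
    """Enumerate every response path of the CAT up to max_depth.

    Nodes carry the item to administer; each response category leads
    either to a child node or to a terminal classification.  The
    enumeration is exhaustive and deterministic (same tie-break as the
    replay loop), so at most n_categories**depth paths exist.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if max_depth > config.max_items:
        raise ValueError("max_depth cannot exceed the item cap")

    def build(responses: dict[int, int], depth: int) -> dict:
        theta = config.entry_theta if not responses else estimate_theta(
            bank, responses, method=config.estimator
        ).theta_hat
        item_id = select_next_item(bank, responses.keys(), theta)
        node = {"item": item_id, "depth": depth, "edges": {}}
        for k in range(bank.n_categories):
            resp = dict(responses)
            resp[item_id] = k
            est = estimate_theta(bank, resp, method=config.estimator)
            if config.estimator == "MLE" and est.boundary:
                est = estimate_theta(bank, resp, method="EAP")
            stop, reason = check_stopping(
                est, config, len(resp), len(bank) - len(resp)
            )
            classification = "elevated" if est.theta_hat > config.cutoff_theta else "low"
            if stop or depth + 1 >= max_depth:
                node["edges"][k] = {
                    "terminal": True,
                    "classification": classification,
                    "reason": reason if stop else "depth_limit",
                    "theta_hat": round(est.theta_hat, 4),
                    "se": round(est.se, 4),
                }
            else:
                node["edges"][k] = {"terminal": False, "child": build(resp, depth + 1)}
        return node

    return build({}, 0)


def tree_to_dot(tree: dict) -> str:
    """Render the decision tree as Graphviz DOT."""
    lines = ["digraph cat {", '  node [shape=box];']
    counter = [0]

    def walk(node: dict) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        lines.append(f'  {nid} [label="item {node["item"]}"];')
        for resp, edge in node["edges"].items():
            if edge["terminal"]:
                tid = f"t{counter[0]}"
                counter[0] += 1
                label = f'{edge["classification"]}\\n(theta={edge["theta_hat"]})'
                shape = "ellipse" if edge["classification"] == "elevated" else "plaintext"
                lines.append(f'  {tid} [label="{label}", shape={shape}];')
                lines.append(f'  {nid} -> {tid} [label="{resp}"];')
            else:
                cid = walk(edge["child"])
                lines.append(f'  {nid} -> {cid} [label="{resp}"];')
        return nid

    walk(tree)
    lines.append("}")
    return "\n".join(lines)


def tree_to_json(tree: dict) -> str:
    return json.dumps(tree, indent=2)
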
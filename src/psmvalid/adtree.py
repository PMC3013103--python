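"""Alternating decision trees: boosted additive rule models.

An ADTree is a collection of base rules learned by boosting.  Each rule
hangs under a *prediction node* (its precondition), tests one feature
against a threshold, and contributes a real-valued prediction in each
branch.  The score of an instance — its *margin* — is the root prediction
value plus the values of every prediction node the instance reaches, so
classification is determined by a collection of paths rather than a single
root-to-leaf path.  A positive margin classifies the instance as true, and
the magnitude is a confidence usable for calibration.

Training follows the boosting formulation: instance weights start uniform,
and each iteration selects the (precondition, feature, threshold) triple
minimizing

    Z = 2 * [ sqrt(W+(c&s) W-(c&s)) + sqrt(W+(c&!s) W-(c&!s)) ] + W(!c)

where ``c`` is the precondition, ``s`` the split predicate and ``W+/-``
weight totals by class.  Prediction values are smoothed log-odds
``0.5 * ln((W+ + eps) / (W- + eps))`` and weights are multiplied by
``exp(-y * r(x))`` for the new rule's contribution ``r``.  Candidate
thresholds are midpoints between consecutive distinct feature values
observed under the precondition.  Ties in Z are broken toward the lowest
precondition node id, then feature index, then threshold, making training
deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_EXPORT_FORMATS = ("text", "dot", "json")


@dataclass(frozen=True)
class AdtRule:
    """One base rule.  Prediction-node ids: 0 is the root; rule ``r``
    creates nodes ``2r - 1`` (left, feature <= threshold) and ``2r``."""
    rule_id: int
    precondition_node: int
    feature: int
    threshold: float
    left_value: float
    right_value: float


@dataclass
class AdtModel:
    root_value: float
    rules: list[AdtRule]
    feature_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_prediction_nodes(self) -> int:
        """Prediction nodes including the root (1 + 2 per rule)."""
        return 1 + 2 * len(self.rules)

    # -- scoring ----------------------------------------------------------
    def margins(self, X) -> np.ndarray:
        """Additive margin scores for a 2-D array of instances."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected shape (n, {len(self.feature_names)}), got {X.shape}")
        out = np.full(X.shape[0], self.root_value, dtype=float)
        reach: dict[int, np.ndarray] = {0: np.ones(X.shape[0], dtype=bool)}
        for r in self.rules:
            at_node = reach[r.precondition_node]
            left = at_node & (X[:, r.feature] <= r.threshold)
            right = at_node & ~left
            out[left] += r.left_value
            out[right] += r.right_value
            reach[2 * r.rule_id - 1] = left
            reach[2 * r.rule_id] = right
        return out

    def margin(self, x) -> float:
        return float(self.margins(np.asarray(x, dtype=float)[None, :])[0])

    def classify(self, X) -> np.ndarray:
        """1 iff margin strictly greater than zero."""
        return (self.margins(X) > 0).astype(int)


def train_adtree(X, y, feature_names: Sequence[str] | None = None,
                 iterations: int = 9, epsilon: float = 1.0,
                 balance_classes: bool = False,
                 seed: int | None = None) -> AdtModel:
    """Train an alternating decision tree.

    ``iterations`` rules are added (default 9, giving 19 prediction nodes —
    small enough to read as a diagram).  ``epsilon`` is the Laplace-style
    smoothing inside the prediction-value log-odds; instance weights are
    initialized to 1 each.  With ``balance_classes`` the positive-class
    weights are rescaled so both classes start with equal total weight.
    ``seed`` is recorded in the model metadata only; training itself is
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be in {0, 1}")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    feature_names = list(feature_names)
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations > 0 and len(set(np.unique(y))) < 2:
        raise ValueError("training requires at least one instance of each class")

    s = np.where(y == 1, 1.0, -1.0)
    n, nf = X.shape
    w = np.ones(n)
    if balance_classes:
        wp, wn = w[s > 0].sum(), w[s < 0].sum()
        if wp > 0 and wn > 0:
            w[s > 0] *= wn / wp

    def logodds(wp: float, wn: float) -> float:
        return 0.5 * math.log((wp + epsilon) / (wn + epsilon))

    root = logodds(w[s > 0].sum(), w[s < 0].sum())
    w = w * np.exp(-s * root)

    # per-feature global sort orders, reused for every precondition subset
    order = np.argsort(X, axis=0, kind="stable")
    reach: dict[int, np.ndarray] = {0: np.ones(n, dtype=bool)}
    rules: list[AdtRule] = []

    for t in range(1, iterations + 1):
        total_w = w.sum()
        best = None  # (Z, node, feature, threshold, a, b, left_mask)
        for node in sorted(reach):
            mask = reach[node]
            if not mask.any():
                continue
            w_not_c = total_w - w[mask].sum()
            for f in range(nf):
                idx = order[:, f]
                idx = idx[mask[idx]]           # node's instances, sorted by f
                vals = X[idx, f]
                if vals[0] == vals[-1]:
                    continue                    # no distinct values to split
                wv = w[idx]
                wp = np.where(s[idx] > 0, wv, 0.0).cumsum()
                wn = np.where(s[idx] > 0, 0.0, wv).cumsum()
                cut = np.nonzero(vals[:-1] < vals[1:])[0]
                thr = 0.5 * (vals[cut] + vals[cut + 1])
                wpl, wnl = wp[cut], wn[cut]
                wpr, wnr = wp[-1] - wpl, wn[-1] - wnl
                z = 2.0 * (np.sqrt(wpl * wnl) + np.sqrt(wpr * wnr)) + w_not_c
                j = int(np.argmin(z))           # first minimum -> lowest threshold
                if best is None or z[j] < best[0]:
                    a = logodds(wpl[j], wnl[j])
                    b = logodds(wpr[j], wnr[j])
                    best = (float(z[j]), node, f, float(thr[j]), a, b)
        if best is None:
            break  # every node is constant in every feature
        _, node, f, threshold, a, b = best
        mask = reach[node]
        left = mask & (X[:, f] <= threshold)
        right = mask & ~left
        w[left] *= np.exp(-s[left] * a)
        w[right] *= np.exp(-s[right] * b)
        rules.append(AdtRule(t, node, f, threshold, a, b))
        reach[2 * t - 1] = left
        reach[2 * t] = right

    return AdtModel(
        root_value=root, rules=rules, feature_names=feature_names,
        meta={"iterations": iterations, "epsilon": epsilon, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Serialization and rendering

def model_to_dict(model: AdtModel) -> dict:
    d = {
        "root_value": model.root_value,
        "feature_names": model.feature_names,
        "rules": [{
            "id": r.rule_id, "precondition_node": r.precondition_node,
            "feature": r.feature, "threshold": r.threshold,
            "left_value": r.left_value, "right_value": r.right_value,
        } for r in model.rules],
        "meta": model.meta,
    }
    return d


def model_from_dict(d: dict) -> AdtModel:
    return AdtModel(
        root_value=float(d["root_value"]),
        rules=[AdtRule(int(r["id"]), int(r["precondition_node"]),
                       int(r["feature"]), float(r["threshold"]),
                       float(r["left_value"]), float(r["right_value"]))
               for r in d["rules"]],
        feature_names=list(d["feature_names"]),
        meta=dict(d.get("meta", {})),
    )


def save_model(model: AdtModel, path: str | Path, extra: dict | None = None) -> None:
    d = model_to_dict(model)
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_model(path: str | Path) -> tuple[AdtModel, dict]:
    """Load a model JSON; returns (model, whole document) so callers can
    pick up extras such as the calibration block."""
    d = json.loads(Path(path).read_text())
    return model_from_dict(d), d


def _children(model: AdtModel) -> dict[int, list[AdtRule]]:
    by_node: dict[int, list[AdtRule]] = {}
    for r in model.rules:
        by_node.setdefault(r.precondition_node, []).append(r)
    return by_node


def export_tree(model: AdtModel, format: str = "text") -> str:
    """Render a model as indented text, Graphviz DOT, or JSON.

    Following the usual diagram convention, each splitter is labelled with
    its feature name followed by the discovery order in parentheses;
    prediction nodes are ellipses and splitters rectangles in DOT output.
    """
    if format not in _EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_EXPORT_FORMATS}")
    if format == "json":
        return json.dumps(model_to_dict(model), indent=2)
    by_node = _children(model)

    if format == "text":
        lines = [f"root: {model.root_value:+.4f}"]

        def walk(node: int, depth: int) -> None:
            for r in by_node.get(node, []):
                name = model.feature_names[r.feature]
                pad = "  " * depth
                lines.append(f"{pad}[{name} ({r.rule_id})] <= {r.threshold:g}")
                lines.append(f"{pad}  yes: {r.left_value:+.4f}")
                walk(2 * r.rule_id - 1, depth + 2)
                lines.append(f"{pad}  no:  {r.right_value:+.4f}")
                walk(2 * r.rule_id, depth + 2)

        walk(0, 1)
        return "\n".join(lines) + "\n"

    # DOT
    lines = ["digraph adtree {",
             f'  p0 [shape=ellipse, label="{model.root_value:+.4f}"];']
    for r in model.rules:
        name = model.feature_names[r.feature]
        lines.append(
            f'  s{r.rule_id} [shape=box, label="{name} ({r.rule_id})\\n'
            f'<= {r.threshold:g}"];')
        lines.append(f'  p{2 * r.rule_id - 1} [shape=ellipse, '
                     f'label="{r.left_value:+.4f}"];')
        lines.append(f'  p{2 * r.rule_id} [shape=ellipse, '
                     f'label="{r.right_value:+.4f}"];')
        lines.append(f"  p{r.precondition_node} -> s{r.rule_id};")
        lines.append(f'  s{r.rule_id} -> p{2 * r.rule_id - 1} [label="y"];')
        lines.append(f'  s{r.rule_id} -> p{2 * r.rule_id} [label="n"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def exponential_loss(model: AdtModel, X, y) -> float:
    """Training-criterion loss sum(exp(-y_pm * margin)); non-increasing in
    boosting iterations on the training set."""
    s = np.where(np.asarray(y) == 1, 1.0, -1.0)
    return float(np.exp(-s * model.margins(X)).sum())
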
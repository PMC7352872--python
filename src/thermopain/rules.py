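"""Separate-and-conquer rule induction for explaining cluster membership.

A small RIPPER-style learner: conjunctive threshold rules for the minority
class are grown greedily by FOIL information gain, pruned by reduced-error
pruning on a held-out third of the training data, and appended until no
positive examples remain or no acceptable rule can be found.  The result is
an ordered rule list with a default class, e.g.

    IF zCPT_baseline <= 0.19 THEN cluster 2
    IF zHPT_baseline <= -1.06 THEN cluster 2
    ELSE cluster 1

which turns an opaque cluster assignment into a human-readable phenotype
definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Condition", "Rule", "RuleSet", "induce_rules"]


@dataclass(frozen=True)
class Condition:
    variable: str
    op: str  # "<=" or ">"
    threshold: float

    def holds(self, values: np.ndarray) -> np.ndarray:
        return values <= self.threshold if self.op == "<=" else values > self.threshold

    def __str__(self) -> str:
        return f"{self.variable} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    label: object

    def covers(self, table: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(table), dtype=bool)
        for cond in self.conditions:
            mask &= cond.holds(table[cond.variable].to_numpy(dtype=float))
        return mask

    def __str__(self) -> str:
        body = " AND ".join(str(c) for c in self.conditions) or "TRUE"
        return f"IF {body} THEN {self.label}"


@dataclass(frozen=True)
class RuleSet:
    """Ordered rule list with a default class; first matching rule wins."""

    rules: tuple[Rule, ...]
    default: object

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.default, dtype=object)
        unassigned = np.ones(len(table), dtype=bool)
        for rule in self.rules:
            hit = rule.covers(table) & unassigned
            out[hit] = rule.label
            unassigned &= ~hit
        return out

    def accuracy(self, table: pd.DataFrame, labels) -> float:
        return float(np.mean(self.predict(table) == np.asarray(labels, dtype=object)))

    def to_text(self) -> str:
        lines = [str(r) for r in self.rules]
        lines.append(f"ELSE {self.default}")
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "rules": [
                {
                    "conditions": [
                        {"variable": c.variable, "op": c.op,
                         "threshold": c.threshold}
                        for c in r.conditions
                    ],
                    "label": r.label,
                }
                for r in self.rules
            ],
            "default": self.default,
        }


def _foil_gain(p: np.ndarray, n: np.ndarray, P: int, N: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        new = np.log2(p / (p + n))
        old = np.log2(P / (P + N)) if P > 0 else 0.0
        gain = p * (new - old)
    return np.where(p > 0, gain, -np.inf)


def _best_condition(X: pd.DataFrame, y: np.ndarray, covered: np.ndarray):
    """Best threshold predicate by FOIL gain over the covered examples."""
    P = int(y[covered].sum())
    N = int(covered.sum() - P)
    best = (-np.inf, None)
    for var in X.columns:
        vals = X[var].to_numpy(dtype=float)[covered]
        ys = y[covered]
        order = np.argsort(vals, kind="stable")
        vals_s, ys_s = vals[order], ys[order]
        uniq, first = np.unique(vals_s, return_index=True)
        if uniq.size < 2:
            continue
        thresholds = (uniq[:-1] + uniq[1:]) / 2.0
        cum_pos = np.concatenate([[0], np.cumsum(ys_s)])
        # examples with value <= threshold t_j are the first first[j+1] sorted
        cut = first[1:]
        p_le = cum_pos[cut].astype(float)
        n_le = cut - p_le
        for op, p_cov, n_cov in (
            ("<=", p_le, n_le),
            (">", P - p_le, N - n_le),
        ):
            gains = _foil_gain(p_cov, n_cov, P, N)
            j = int(np.argmax(gains))
            if gains[j] > best[0] + 1e-12:
                best = (float(gains[j]), Condition(var, op, float(thresholds[j])))
    return best[1] if np.isfinite(best[0]) and best[0] > 0 else None


def _grow_rule(X: pd.DataFrame, y: np.ndarray) -> tuple[Condition, ...]:
    conditions: list[Condition] = []
    covered = np.ones(len(X), dtype=bool)
    while (y[covered] == 0).any():
        cond = _best_condition(X, y, covered)
        if cond is None:
            break
        conditions.append(cond)
        covered &= cond.holds(X[cond.variable].to_numpy(dtype=float))
        if not covered.any():
            break
    return tuple(conditions)


def _prune_metric(conds, X: pd.DataFrame, y: np.ndarray) -> float:
    mask = np.ones(len(X), dtype=bool)
    for c in conds:
        mask &= c.holds(X[c.variable].to_numpy(dtype=float))
    p = int(y[mask].sum())
    n = int(mask.sum()) - p
    return (p - n) / (p + n) if p + n else -1.0


def _rule_significant(conds, X: pd.DataFrame, y: np.ndarray,
                      alpha: float) -> bool:
    """Held-out check that a rule beats guessing at the class prior.

    One-sided binomial test of the rule's positive hits against the prior
    positive rate; keeps noise-fitted rules out of the list.
    """
    from scipy.stats import binomtest

    mask = np.ones(len(X), dtype=bool)
    for c in conds:
        mask &= c.holds(X[c.variable].to_numpy(dtype=float))
    covered = int(mask.sum())
    if covered == 0:
        return False
    hits = int(y[mask].sum())
    prior = float(y.mean())
    if prior in (0.0, 1.0):
        return prior == 1.0
    return binomtest(hits, covered, prior,
                     alternative="greater").pvalue < alpha


def induce_rules(table: pd.DataFrame, labels, seed: int = 0,
                 prune_fraction: float = 1 / 3,
                 stop_alpha: float = 0.05) -> RuleSet:
    """Induce an ordered threshold-rule list separating two clusters.

    Rules target the minority class; candidate thresholds are midpoints of
    sorted feature values; each grown rule is pruned (suffix removal) to
    maximize (p - n)/(p + n) on a held-out third, and rule addition stops
    when a pruned rule misclassifies more than it explains.  Single-class
    input yields an empty rule list whose default is that class.
    """
    y_raw = np.asarray(labels)
    classes, counts = np.unique(y_raw, return_counts=True)
    if classes.size == 1:
        return RuleSet(rules=(), default=classes[0].item()
                       if hasattr(classes[0], "item") else classes[0])
    if classes.size != 2:
        raise ValueError("rule induction expects binary labels")
    positive = classes[np.argmin(counts)]
    default = classes[classes != positive][0]
    X = table.select_dtypes(include=[np.number]).copy()
    if X.shape[1] == 0:
        raise ValueError("no numeric features available")
    y = (y_raw == positive).astype(int)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))

    remaining = np.ones(len(X), dtype=bool)
    rules: list[Rule] = []
    while y[remaining].sum() > 0:
        idx = np.flatnonzero(remaining)
        # stratified grow/prune split of the remaining examples
        grow_idx, prune_idx = [], []
        for cls in (0, 1):
            members = idx[y[idx] == cls]
            members = members[rng.permutation(members.size)]
            n_prune = int(round(prune_fraction * members.size))
            prune_idx.extend(members[:n_prune])
            grow_idx.extend(members[n_prune:])
        grow_idx, prune_idx = np.sort(grow_idx), np.sort(prune_idx)
        if y[grow_idx].sum() == 0:
            break
        conds = _grow_rule(X.iloc[grow_idx], y[grow_idx])
        if not conds:
            break
        # reduced-error pruning: best prefix on the held-out part
        if prune_idx.size:
            scores = [_prune_metric(conds[:m], X.iloc[prune_idx], y[prune_idx])
                      for m in range(1, len(conds) + 1)]
            best_m = int(np.argmax(scores)) + 1
            if scores[best_m - 1] < 0:  # worse than useless: stop
                break
            conds = conds[:best_m]
            if not _rule_significant(conds, X.iloc[prune_idx], y[prune_idx],
                                     stop_alpha):
                break
        rule = Rule(conditions=conds, label=positive.item()
                    if hasattr(positive, "item") else positive)
        rules.append(rule)
        remaining &= ~rule.covers(X)
        if not remaining.any():
            break

    ruleset = RuleSet(rules=tuple(rules), default=default.item()
                      if hasattr(default, "item") else default)
    # guardrail: never fall below the majority-class training baseline
    baseline = counts.max() / counts.sum()
    while rules and ruleset.accuracy(X, y_raw) < baseline:
        rules.pop()
        ruleset = RuleSet(rules=tuple(rules), default=ruleset.default)
    return ruleset
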
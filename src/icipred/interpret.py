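"""Shapley-value attribution of predictions to patient-side inputs.

Attribution quantifies how much each input feature (a gene's expression
or a pathway score) moves the model output away from a base value — the
expected output over a background set — for each explained sample.  Two
estimators are provided:

* ``exact``: full 2^m coalition enumeration (m ≤ 15) with absent
  features replaced by background draws (interventional marginalization).
  Satisfies the Shapley axioms to numerical precision.
* ``sampled``: kernel-style weighted least squares over seeded coalition
  draws, with the full and empty coalitions pinned so the local-accuracy
  identity base + Σ attributions = model output holds exactly.

For high-dimensional gene inputs, attribution is restricted to a feature
subset (top-variance genes plus all pathway scores by default); the
remaining inputs stay fixed at the explained sample's values and are
absorbed into the base value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ValidationError

__all__ = [
    "AttributionResult",
    "shapley_values",
    "global_importance",
    "fold_intersection",
    "waterfall_export",
    "top_variance_features",
]

EXACT_MAX_FEATURES = 15
LOCAL_ACCURACY_TOL_EXACT = 1e-6
LOCAL_ACCURACY_TOL_SAMPLED = 0.02


@dataclass
class AttributionResult:
    """Per-(sample, feature) Shapley values with the shared base value."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray        # (n_samples, m)
    base_values: np.ndarray   # (n_samples,) expected output over background
    model_outputs: np.ndarray  # (n_samples,)
    method: str               # "exact" | "sampled"

    def __post_init__(self):
        n, m = len(self.sample_ids), len(self.feature_names)
        self.base_values = np.atleast_1d(
            np.asarray(self.base_values, dtype=np.float64))
        if self.values.shape != (n, m) or self.base_values.shape != (n,):
            raise ValidationError("attribution matrix shape mismatch")
        tol = (LOCAL_ACCURACY_TOL_EXACT if self.method == "exact"
               else LOCAL_ACCURACY_TOL_SAMPLED)
        gap = np.abs(self.base_values + self.values.sum(axis=1)
                     - self.model_outputs)
        if np.any(gap > tol):
            raise ValidationError(
                f"local accuracy violated: max gap {gap.max():.3g} > {tol}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, f, self.values[i, j])
                for i, s in enumerate(self.sample_ids)
                for j, f in enumerate(self.feature_names)]
        return pd.DataFrame(rows, columns=["sample", "feature", "value"])


def _coalition_value(model_fn, x: np.ndarray, background: np.ndarray,
                     feature_idx: np.ndarray, masks: np.ndarray
                     ) -> np.ndarray:
    """v(S) for a batch of coalition masks, one explained sample.

    masks is (n_masks, m) boolean; features outside ``feature_idx`` stay
    at x's values.  Returns the background-averaged model output per mask.
    """
    n_bg = background.shape[0]
    n_masks = masks.shape[0]
    X = np.repeat(x[None, :], n_masks * n_bg, axis=0)
    mask_rows = np.repeat(masks, n_bg, axis=0)       # (n_masks*n_bg, m)
    bg_sub = np.tile(background[:, feature_idx], (n_masks, 1))
    sub = X[:, feature_idx]
    sub[~mask_rows] = bg_sub[~mask_rows]
    X[:, feature_idx] = sub
    out = np.asarray(model_fn(X), dtype=np.float64)
    return out.reshape(n_masks, n_bg).mean(axis=1)


def _exact_shapley(model_fn, x: np.ndarray, background: np.ndarray,
                   feature_idx: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = len(feature_idx)
    masks = np.array([[bool(s >> i & 1) for i in range(m)]
                      for s in range(2 ** m)])
    v = _coalition_value(model_fn, x, background, feature_idx, masks)
    phi = np.zeros(m)
    fact = [math.factorial(i) for i in range(m + 1)]
    sizes = masks.sum(axis=1)
    for i in range(m):
        without = ~masks[:, i]
        s_ids = np.flatnonzero(without)
        for s in s_ids:
            k = int(sizes[s])
            w = fact[k] * fact[m - k - 1] / fact[m]
            phi[i] += w * (v[s | (1 << i)] - v[s])
    return phi, float(v[0]), float(v[-1])


def _sampled_shapley(model_fn, x: np.ndarray, background: np.ndarray,
                     feature_idx: np.ndarray, budget: int,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, float, float]:
    """Kernel-weighted least squares over sampled coalitions.

    The empty and full coalitions anchor the base value and the output;
    the sum constraint is enforced by variable elimination, so local
    accuracy is exact by construction.
    """
    m = len(feature_idx)
    if budget < 2 * m + 2:
        raise ValidationError(
            f"budget {budget} too small: need >= {2 * m + 2} coalition "
            f"evaluations for a stable weighted regression")
    # always include all singleton and all-but-one coalitions
    masks = [np.zeros(m, bool), np.ones(m, bool)]
    for i in range(m):
        one = np.zeros(m, bool)
        one[i] = True
        masks.append(one)
        masks.append(~one)
    n_random = budget - len(masks)
    sizes = np.arange(1, m)
    kw = (m - 1) / (sizes * (m - sizes))
    kw = kw / kw.sum()
    for _ in range(max(n_random, 0)):
        k = rng.choice(sizes, p=kw)
        mask = np.zeros(m, bool)
        mask[rng.choice(m, size=k, replace=False)] = True
        masks.append(mask)
    masks = np.array(masks)
    v = _coalition_value(model_fn, x, background, feature_idx, masks)
    v0, v1 = float(v[0]), float(v[1])

    interior = [i for i in range(len(masks))
                if 0 < masks[i].sum() < m]
    Z = masks[interior].astype(np.float64)
    y = v[interior] - v0
    ks = Z.sum(axis=1)
    w = (m - 1) / (ks * (m - ks))
    # eliminate the last feature via Σ phi = v1 - v0
    total = v1 - v0
    Zr = Z[:, :-1] - Z[:, -1:]
    yr = y - Z[:, -1] * total
    A = (Zr * w[:, None]).T @ Zr + 1e-10 * np.eye(m - 1)
    b = (Zr * w[:, None]).T @ yr
    phi_head = np.linalg.solve(A, b)
    phi = np.append(phi_head, total - phi_head.sum())
    return phi, v0, v1


def top_variance_features(x_matrix: np.ndarray, feature_names: list[str],
                          n_top: int) -> list[int]:
    """Indices of the ``n_top`` highest-variance features."""
    var = np.asarray(x_matrix).var(axis=0)
    order = np.argsort(-var, kind="stable")
    return sorted(order[:n_top].tolist())


def shapley_values(model_fn, background: np.ndarray, samples: np.ndarray,
                   sample_ids: list[str], feature_names: list[str],
                   method: str = "sampled", budget: int = 2048,
                   seed: int = 0, feature_idx: np.ndarray | None = None
                   ) -> AttributionResult:
    """Shapley attributions for each row of ``samples``.

    ``model_fn`` maps an (n, n_features) array to n outputs; ``background``
    supplies the marginalization draws.  ``feature_idx`` optionally
    restricts attribution to a subset of columns (all others held at the
    explained sample's values); ``feature_names`` then names that subset.
    """
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    if background.shape[0] == 0:
        raise ValidationError("background must be non-empty")
    if feature_idx is None:
        feature_idx = np.arange(samples.shape[1])
    feature_idx = np.asarray(feature_idx, dtype=np.int64)
    m = len(feature_idx)
    if len(feature_names) != m:
        raise ValidationError("feature_names must match attributed features")
    if method == "exact" and m > EXACT_MAX_FEATURES:
        raise ValidationError(
            f"exact method limited to {EXACT_MAX_FEATURES} features, "
            f"got {m}")
    if method not in ("exact", "sampled"):
        raise ValidationError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    values = np.zeros((samples.shape[0], m))
    bases, outs = [], []
    for i, x in enumerate(samples):
        if method == "exact":
            phi, v0, v1 = _exact_shapley(model_fn, x, background,
                                         feature_idx)
        else:
            phi, v0, v1 = _sampled_shapley(model_fn, x, background,
                                           feature_idx, budget, rng)
        values[i] = phi
        bases.append(v0)
        outs.append(v1)
    return AttributionResult(list(sample_ids), list(feature_names), values,
                             np.array(bases), np.array(outs), method)


def global_importance(result: AttributionResult) -> pd.DataFrame:
    """Mean |Shapley| per feature, descending; ties broken by name."""
    if result.values.size == 0:
        raise ValidationError("empty attribution result")
    imp = np.abs(result.values).mean(axis=0)
    df = pd.DataFrame({"feature": result.feature_names, "importance": imp})
    return df.sort_values(["importance", "feature"],
                          ascending=[False, True],
                          kind="stable").reset_index(drop=True)


def fold_intersection(per_fold_rankings: list[list[str]], top_k: int
                      ) -> set[str]:
    """Intersection of each fold's top-k feature sets (may be empty)."""
    if len(per_fold_rankings) < 2:
        raise ValidationError("need rankings from at least 2 folds")
    sets = [set(r[:top_k]) for r in per_fold_rankings]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def waterfall_export(result: AttributionResult, sample_id: str,
                     top_n: int = 10) -> pd.DataFrame:
    """Ordered signed contributions for one sample plus a remainder row.

    Rows (with the base value) sum to the model output for the sample.
    """
    i = result.sample_ids.index(sample_id)
    row = result.values[i]
    order = np.argsort(-np.abs(row), kind="stable")
    top = order[:top_n]
    rest = order[top_n:]
    rows = [("base", float(result.base_values[i]))]
    rows += [(result.feature_names[j], float(row[j])) for j in top]
    rows.append(("remainder", float(row[rest].sum())))
    rows.append(("model_output", float(result.model_outputs[i])))
    df = pd.DataFrame(rows, columns=["term", "value"])
    contrib = df.iloc[:-1]["value"].sum()
    if abs(contrib - result.model_outputs[i]) > LOCAL_ACCURACY_TOL_SAMPLED:
        raise ValidationError("waterfall rows do not sum to model output")
    return df
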
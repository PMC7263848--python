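"""AIC-based multimodel comparison: Akaike weights and pairwise
Kullback--Leibler discrepancy ratios.

Given candidate models fitted to the same records, the Akaike weight of
model i is

    w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2),   Delta_i = AIC_i - min_j AIC_j,

interpretable as the relative support for model i within the candidate
set.  The pairwise KL discrepancy ratio between two adjacent models in a
selection sequence is the two-model normalisation of the same quantity:
the probability that the better of the pair is to be preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def akaike_weights(aic) -> np.ndarray:
    """Akaike weights from AIC values (or directly from ΔAIC values).

    Computed with the max-subtraction trick so that very large Δ underflow
    to exact 0 rather than producing NaN.
    """
    aic = np.asarray(aic, dtype=float)
    if aic.size == 0 or not np.all(np.isfinite(aic)):
        raise ValueError("akaike_weights requires a non-empty set of finite AIC values")
    delta = aic - aic.min()
    un = np.exp(-delta / 2.0)
    return un / un.sum()


def kl_ratio(aic_a: float, aic_b: float) -> float:
    """Probability that model b is preferred over model a (pairwise weight).

    Symmetric complement: kl_ratio(a, b) + kl_ratio(b, a) = 1, and for two
    models it coincides with the Akaike weight of b.
    """
    if not (np.isfinite(aic_a) and np.isfinite(aic_b)):
        raise ValueError("kl_ratio requires finite AIC values")
    m = min(aic_a, aic_b)
    ea = np.exp(-(aic_a - m) / 2.0)
    eb = np.exp(-(aic_b - m) / 2.0)
    return float(eb / (ea + eb))


def format_weight(w: float) -> str:
    """Format a weight the way selection tables print them.

    Two decimals above 0.01, scientific notation with 3 significant digits
    below, and "<1e-300" for exact-zero underflow.
    """
    if w == 0.0:
        return "<1e-300"
    if w >= 0.01:
        return f"{w:.2f}"
    return f"{w:.2E}"


@dataclass
class ModelComparisonTable:
    """Ordered model comparison with ΔAIC, Akaike weights and pairwise KL."""

    labels: list
    aic: np.ndarray
    delta_aic: np.ndarray
    weights: np.ndarray
    kl_vs_next: np.ndarray  # last entry NaN (no following column)
    n_obs: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.labels,
                "aic": self.aic,
                "delta_aic": self.delta_aic,
                "akaike_weight": self.weights,
                "kl_vs_next": self.kl_vs_next,
            }
        )

    def to_wide_frame(self) -> pd.DataFrame:
        """Table-style wide layout: one column per model, stat rows."""
        rows = {
            "AIC": [f"{a:.1f}" for a in self.aic],
            "dAIC": [f"{d:.4g}" for d in self.delta_aic],
            "weights AIC": [format_weight(w) for w in self.weights],
            "Kullback-Leibler": [
                "-" if np.isnan(k) else f"{k:.2f}" for k in self.kl_vs_next
            ],
        }
        return pd.DataFrame(rows, index=self.labels).T

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_models(models, labels=None) -> ModelComparisonTable:
    """Build a comparison table from fitted models or raw AIC values.

    `models` may be a sequence of objects with `.aic` (and optionally
    `.n_obs`) attributes, or a sequence of AIC floats.  Models must have
    been fitted to the identical record set; differing `n_obs` raises,
    since AIC values are then not comparable.
    """
    aics, ns = [], []
    for m in models:
        if hasattr(m, "aic"):
            aics.append(float(m.aic))
            ns.append(getattr(m, "n_obs", None))
        else:
            aics.append(float(m))
            ns.append(None)
    known_ns = {n for n in ns if n is not None}
    if len(known_ns) > 1:
        raise ValueError(f"models fitted to differing record counts {sorted(known_ns)}")
    aic = np.asarray(aics)
    if labels is None:
        labels = [f"model {i}" for i in range(len(aic))]
    weights = akaike_weights(aic)
    delta = aic - aic.min()
    kl = np.full(len(aic), np.nan)
    for i in range(len(aic) - 1):
        # probability that the model in column i+1 is preferred over column i
        kl[i] = kl_ratio(aic[i], aic[i + 1])
    return ModelComparisonTable(
        labels=list(labels),
        aic=aic,
        delta_aic=delta,
        weights=weights,
        kl_vs_next=kl,
        n_obs=(known_ns.pop() if known_ns else None),
    )


@dataclass
class TermAddition:
    """One step of a nested model sequence: add `term` to the named blocks."""

    term: str
    blocks: tuple = ("asym", "r0", "lrc")
    interactions: tuple = ()


def build_model_sequence(base_spec, additions):
    """Cumulative nested specs from a base spec and ordered term additions.

    Each addition appends a term (and optional sex interactions) to the
    named parameter blocks of a copy of the previous spec, mirroring the
    "Y" pattern of a stepwise selection table.  Duplicate terms within a
    block raise.
    """
    specs = [base_spec]
    current = base_spec
    for add in additions:
        current = current.with_terms(add.term, blocks=add.blocks)
        for inter in add.interactions:
            current = current.with_terms(inter, blocks=add.blocks)
        specs.append(current)
    return specs
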
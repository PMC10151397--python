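"""Per-spot treatment response: linear model, Bonferroni, DE selection.

The treatment model regresses each spot's log2 intensity on a two-level
treatment indicator (ordinary least squares; the slope t test is the
pooled two-sample t test). Genotype is deliberately ignored here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ParameterError, ValidationError
from .io_core import ExpressionMatrix

P_FLOOR = 1e-300


@dataclass
class DEResult:
    spot_id: str
    lfc: float  # perturbed minus control group mean, log2 units
    p_value: float
    p_adj: float  # Bonferroni
    residual_variance: float
    significant: bool


def treatment_model(
    expr: ExpressionMatrix,
    control: str | None = None,
    p_adj_max: float = 0.05,
) -> list[DEResult]:
    """OLS of every spot on the treatment indicator, Bonferroni-adjusted.

    ``control`` names the reference level (default: first level seen in the
    metadata); the log2 fold change is perturbed minus control mean.
    """
    levels = expr.treatments
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 treatment levels, got {levels}")
    if control is None:
        control = levels[0]
    elif control not in levels:
        raise ValidationError(f"control level {control!r} not among {levels}")
    perturbed = next(t for t in levels if t != control)

    t_lab = expr.metadata["treatment"].to_numpy()
    a = expr.values[:, t_lab == control]
    b = expr.values[:, t_lab == perturbed]
    n0, n1 = a.shape[1], b.shape[1]
    if n0 < 2 or n1 < 2:
        raise ValidationError("each treatment level needs >= 2 samples")

    lfc = b.mean(axis=1) - a.mean(axis=1)
    df = n0 + n1 - 2
    ss = a.var(axis=1, ddof=1) * (n0 - 1) + b.var(axis=1, ddof=1) * (n1 - 1)
    resid_var = ss / df
    se = np.sqrt(resid_var * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    m = len(expr.spots)
    p_adj = np.minimum(1.0, p * m)
    return [
        DEResult(
            spot_id=s,
            lfc=float(lfc[i]),
            p_value=float(p[i]),
            p_adj=float(p_adj[i]),
            residual_variance=float(resid_var[i]),
            significant=bool(p_adj[i] < p_adj_max),
        )
        for i, s in enumerate(expr.spots)
    ]


def select_de(
    results: list[DEResult], p_adj_max: float = 0.05, min_abs_lfc: float = 2.0
) -> tuple[list[str], list[str]]:
    """Split spots into up- and down-regulated lists.

    Selection uses strict inequalities: adjusted p below ``p_adj_max`` and
    |log2 fold change| strictly above ``min_abs_lfc``.
    """
    up = [r.spot_id for r in results if r.p_adj < p_adj_max and r.lfc > min_abs_lfc]
    down = [r.spot_id for r in results if r.p_adj < p_adj_max and r.lfc < -min_abs_lfc]
    return up, down


def collapse_to_genes(spot_ids: list[str], spot_to_gene) -> list[str]:
    """Gene-level DE list: a gene is DE if any of its spots is selected."""
    return sorted({spot_to_gene(s) for s in spot_ids})


def overlap_test(selected: set, target: set, universe: set) -> tuple[float, int]:
    """Upper-tail hypergeometric test of the selected/target gene overlap.

    Returns (P(X >= overlap), overlap) for X hypergeometric with
    population |universe|, |selected| successes and |target| draws.
    """
    if not universe:
        raise ParameterError("empty universe")
    if not target <= universe or not selected <= universe:
        raise ValidationError("selected and target sets must be within the universe")
    k = len(selected & target)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(selected), len(target)))
    return min(p, 1.0), k
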
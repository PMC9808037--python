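"""Cross-model consistency of pollutant associations.

A pollutant shows a *consistent association* when it is selected by both the
non-spatial and the spatial Poisson lasso and additionally ranks highly in
the random-forest permutation importances — three models with different
assumptions (no spatial structure / explicit spatial terms / nonlinear
nonparametric) agreeing on the same exposure.
"""

from __future__ import annotations

import pandas as pd

from .forest import ForestResult
from .lasso import LassoResult

__all__ = ["compare_models"]


def compare_models(
    nonspatial: LassoResult,
    spatial: LassoResult,
    forest: ForestResult,
    rf_rank_threshold: int = 2,
) -> pd.DataFrame:
    """Feature-wise selection table with a ``consistent`` flag.

    Rows are the penalized (pollutant) features of the lassos; the forest
    must have been fitted on a feature set containing them. ``consistent`` is
    True when the feature is selected by both lassos at their chosen lambdas
    and its forest rank is <= ``rf_rank_threshold``.
    """
    pen_ns = [f for f, pf in zip(nonspatial.feature_names, nonspatial.penalty_factor) if pf > 0]
    pen_sp = [f for f, pf in zip(spatial.feature_names, spatial.penalty_factor) if pf > 0]
    if pen_ns != pen_sp:
        raise ValueError("lasso models were fitted on different penalized feature sets")
    missing = [f for f in pen_ns if f not in forest.feature_names]
    if missing:
        raise ValueError(f"forest lacks features: {missing}")

    sel_ns = set(nonspatial.selected())
    sel_sp = set(spatial.selected())
    ranks = forest.ranks()
    table = pd.DataFrame(
        {
            "feature": pen_ns,
            "selected_nonspatial": [f in sel_ns for f in pen_ns],
            "selected_spatial": [f in sel_sp for f in pen_ns],
            "rf_rank": [int(ranks[f]) for f in pen_ns],
        }
    )
    table["consistent"] = (
        table["selected_nonspatial"]
        & table["selected_spatial"]
        & (table["rf_rank"] <= rf_rank_threshold)
    )
    return table
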
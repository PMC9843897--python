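"""Hypergeometric over-representation analysis with BH correction."""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust
from .errors import ValidationError
from .io_formats import TermMap

__all__ = ["over_representation"]


def over_representation(
    study_set: set[str],
    term_map: TermMap,
    universe: set[str],
    min_term_size: int | None = None,
    max_term_size: int | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each term against the study set.

    p = P[X >= k] with X ~ Hypergeometric(N, K, n) where N is the universe
    size, K the term size within the universe, n the study size and k the
    overlap. Terms with k = 0 are not tested; BH runs across tested terms.
    """
    study = set(study_set)
    universe = set(universe)
    offenders = sorted(study - universe)
    if offenders:
        raise ValidationError(f"study genes outside the universe: {offenders}")
    n = len(study)
    n_universe = len(universe)
    rows = []
    for term_id in sorted(term_map.terms):
        members = term_map.terms[term_id] & universe
        big_k = len(members)
        if big_k == 0:
            continue
        if min_term_size is not None and big_k < min_term_size:
            continue
        if max_term_size is not None and big_k > max_term_size:
            continue
        k = len(members & study)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_map.names[term_id],
                "overlap": k,
                "study_size": n,
                "term_size": big_k,
                "universe_size": n_universe,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "overlap", "study_size",
            "term_size", "universe_size", "p_value",
        ],
    )
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df
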
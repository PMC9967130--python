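"""Over-representation statistics and list-overlap arithmetic.

Enrichment of a query list against named gene sets uses the one-sided
("greater") Fisher exact test, computed as the hypergeometric survival
function of the 2x2 overlap table, with Benjamini-Hochberg adjustment
across sets.  The background universe defaults to all quantified proteins
(standard over-representation practice), and both sets and query are
intersected with it; identifiers are case-normalized to upper case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def _norm(ids) -> set[str]:
    return {str(x).strip().upper() for x in ids if str(x).strip()}


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_sets(
        cls,
        sets: dict[str, set[str] | list[str]],
        universe: set[str] | list[str],
        descriptions: dict[str, str] | None = None,
    ) -> "GeneSetCollection":
        uni = _norm(universe)
        cleaned: dict[str, set[str]] = {}
        for name, members in sets.items():
            if not str(name).strip():
                raise ValueError("gene set with empty name")
            m = _norm(members)
            dropped = m - uni
            if dropped:
                warnings.warn(
                    f"gene set {name!r}: {len(dropped)} members outside the universe dropped",
                    stacklevel=2,
                )
            cleaned[name] = m & uni
        return cls(sets=cleaned, universe=uni, descriptions=descriptions or {})


def fisher_enrichment(query, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in every set.

    p = P[overlap >= observed] from the hypergeometric distribution of the
    2x2 table (universe N, set K, query n, overlap k); BH adjustment across
    all sets; rows sorted by adjusted p then name.
    """
    q = _norm(query)
    outside = q - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query identifiers outside the universe dropped", stacklevel=2
        )
        q = q & collection.universe
    if not q:
        raise ValueError("empty query after restriction to the universe")
    n_universe = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, n_universe, len(members), len(q)))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "query_size": len(q),
                "set_size": len(members),
                "universe_size": n_universe,
                "p": min(max(p, np.nextafter(0, 1)), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p_adj", "set"], kind="stable").set_index("set")
    assert (out["p_adj"] >= out["p"] - 1e-15).all()
    return out


def list_overlap(query, references: dict[str, set[str] | list[str]]) -> pd.DataFrame:
    """Pairwise overlap of a query list against reference lists.

    Reports the overlap count, its percentage of the query, and the union
    size for each reference, plus a final row for the union of all
    references (the multi-database overlap view).
    """
    q = _norm(query)
    rows = []
    union_all: set[str] = set()
    for name, ref in references.items():
        r = _norm(ref)
        union_all |= r
        inter = q & r
        rows.append(
            {
                "reference": name,
                "overlap": len(inter),
                "query_size": len(q),
                "reference_size": len(r),
                "union_size": len(q | r),
                "percent_of_query": 100.0 * len(inter) / len(q) if q else 0.0,
            }
        )
    if len(references) > 1:
        inter = q & union_all
        rows.append(
            {
                "reference": "__union__",
                "overlap": len(inter),
                "query_size": len(q),
                "reference_size": len(union_all),
                "union_size": len(q | union_all),
                "percent_of_query": 100.0 * len(inter) / len(q) if q else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("reference")
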
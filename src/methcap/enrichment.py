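"""Fisher's-exact (hypergeometric tail) gene-set over-representation with BH FDR."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from methcap.diffmeth import bh_adjust
from methcap.methio import ValidationError

log = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 0.01


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared background universe."""

    sets: dict[str, tuple[str, frozenset[str]]]  # set_id -> (name, members)
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("empty universe")
        for sid, (_, members) in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValidationError(
                    f"set {sid}: members outside universe, e.g. {sorted(extra)[:3]}"
                )


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read GMT lines (set_id<TAB>description<TAB>gene...); universe defaults
    to the union of all member genes when not given."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "rt") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line with < 3 fields: {line[:60]!r}")
            sid, desc, genes = fields[0], fields[1], fields[2:]
            sets[sid] = (desc, frozenset(g for g in genes if g))
    if universe is None:
        universe = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    else:
        universe = frozenset(universe)
        sets = {
            sid: (desc, members & universe) for sid, (desc, members) in sets.items()
        }
    return GeneSetCollection(sets=sets, universe=universe)


def fisher_enrich(query_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided over-representation test per set.

    p = P(X >= k) under Hypergeometric(N=universe size, K=set size,
    n=query-in-universe size); BH adjustment across all tested sets; rows
    sorted by adjusted p.  Query genes outside the universe are dropped
    with a log message.
    """
    query = set(query_genes)
    dropped = query - collection.universe
    if dropped:
        log.info("dropping %d query genes outside the universe", len(dropped))
    query &= collection.universe
    if not query:
        raise ValidationError("query has no genes in the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for sid, (name, members) in collection.sets.items():
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(
                set_id=sid,
                name=name,
                k=k,
                K=K,
                n=n,
                N=N,
                gene_ratio=k / n,
                p=min(p, 1.0),
            )
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p"] < SIGNIFICANCE_THRESHOLD
    df = df.sort_values(["p_adj", "p", "set_id"], kind="mergesort").reset_index(drop=True)
    return df
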
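"""Target-table filtering, cluster common targets, and hypergeometric
gene-set enrichment.

Target predictions arrive as a TSV of (miRNA, gene) edges in the style of a
TargetScan summary file; gene sets arrive in GMT format.  miRNA ids are
normalized (lower case, species prefix such as ``mmu-`` stripped) before
matching, because prediction tables and miRBase use different dialects of
the same name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from scipy import stats

# a species code (mmu-, hsa-, ...) is stripped only when followed by the
# mir/let stem, so "miR-129-3p" itself is left intact
_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(mir|let))", re.IGNORECASE)


def normalize_mirna_id(mirna_id: str) -> str:
    """Canonical form for matching: lower case, species prefix removed."""
    return _SPECIES_PREFIX.sub("", mirna_id.strip().lower())


def read_target_table(
    path, mirna_col: str = "miRNA", gene_col: str = "gene", sep: str = "\t"
) -> pd.DataFrame:
    """Read a miRNA -> gene target table; deduplicates (miRNA, gene) pairs."""
    df = pd.read_csv(path, sep=sep)
    if mirna_col not in df.columns or gene_col not in df.columns:
        raise ValueError(
            f"target table needs columns {mirna_col!r} and {gene_col!r}; "
            f"found {list(df.columns)}"
        )
    out = df.rename(columns={mirna_col: "mirna_id", gene_col: "gene_symbol"})
    return out.drop_duplicates(subset=["mirna_id", "gene_symbol"]).reset_index(
        drop=True
    )


def filter_targets(edges: pd.DataFrame, de_mirnas) -> pd.DataFrame:
    """Keep edges whose miRNA is differentially expressed (id-normalized match)."""
    wanted = {normalize_mirna_id(m) for m in de_mirnas}
    keep = edges["mirna_id"].map(normalize_mirna_id).isin(wanted)
    return edges[keep].reset_index(drop=True)


def common_targets(cluster_mirnas, edges: pd.DataFrame) -> tuple[set, list[str]]:
    """Genes targeted by every miRNA of a cluster.

    Returns ``(intersection, members_without_edges)``; a member absent from
    the table forces an empty intersection and is reported in the flag list.
    """
    members = list(cluster_mirnas)
    if not members:
        raise ValueError("cluster must be non-empty")
    by_mirna = edges.assign(_norm=edges["mirna_id"].map(normalize_mirna_id))
    flagged = []
    common: set | None = None
    for m in members:
        targets = set(
            by_mirna.loc[by_mirna["_norm"] == normalize_mirna_id(m), "gene_symbol"]
        )
        if not targets:
            flagged.append(m)
        common = targets if common is None else (common & targets)
    if flagged:
        return set(), flagged
    return common or set(), flagged


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file: one set per line, name TAB description TAB genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


@dataclass
class GeneSetCollection:
    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        for name, genes in self.sets.items():
            if not genes <= self.universe:
                raise ValueError(f"gene set {name!r} not contained in universe")


def hypergeom_enrich(
    query_genes, collection: GeneSetCollection, alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query against each gene set.

    For a universe of N genes, a set of K, and a query of n with k hits,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Query genes outside the
    universe are dropped (with a warning column in mind, they are simply
    excluded from n).  Significance is p < alpha, uncorrected by default.
    """
    query = set(query_genes)
    inside = query & collection.universe
    N = len(collection.universe)
    n = len(inside)
    rows = []
    for name, genes in sorted(collection.sets.items()):
        K = len(genes)
        k = len(inside & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "k", "n", "K", "N", "p"])
    if bh_correct and len(df):
        from .diffexpr import bh_adjust

        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df
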
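"""Cell-type-specific network filtering by expression.

The pathology-specific network is restricted per cell type to nodes whose
transcript abundance in that cell exceeds a threshold (default > 1.0 in
normalized-TPM-like units, the conventional "expressed" call for Human
Protein Atlas-style data).  Genes absent from the expression table are
treated as not expressed and dropped with a logged count; measured panel
mediators are retained regardless, since they are extracellular species
that anchor the pruning whether or not this cell transcribes them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .network import SignalingNetwork, _key
from .pruning import MediatorPanel

logger = logging.getLogger(__name__)

#: HPA-convention expression call: abundance strictly greater than 1 nTPM.
DEFAULT_THRESHOLD = 1.0


class ExpressionTable:
    """Gene/protein abundance per cell type (nonnegative, TPM-like units).

    Backed by a long-format DataFrame with columns ``id``, ``cell_type``,
    ``abundance``.  Identifier lookup is case-insensitive, matching the
    network's identifier convention.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"id", "cell_type", "abundance"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        df = df.loc[:, ["id", "cell_type", "abundance"]].copy()
        df["abundance"] = pd.to_numeric(df["abundance"])
        if (df["abundance"] < 0).any():
            raise ValueError("abundances must be nonnegative")
        if (df["cell_type"].astype(str).str.len() == 0).any():
            raise ValueError("cell type labels must be non-empty")
        df["_key"] = df["id"].astype(str).str.casefold()
        if df.duplicated(["_key", "cell_type"]).any():
            dupes = df.loc[df.duplicated(["_key", "cell_type"]), "id"].unique()
            raise ValueError(f"duplicate ids within a cell type: {list(dupes)[:5]}")
        self.df = df

    @classmethod
    def from_long(cls, path: str | Path) -> "ExpressionTable":
        """Read TSV/CSV with columns id, cell_type, abundance."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep))

    @classmethod
    def from_wide(cls, path: str | Path) -> "ExpressionTable":
        """Read a wide matrix: rows = ids, columns = cell types."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        wide = pd.read_csv(path, sep=sep, index_col=0)
        long = wide.reset_index(names="id").melt(
            id_vars="id", var_name="cell_type", value_name="abundance"
        )
        return cls(long)

    @classmethod
    def from_records(cls, records) -> "ExpressionTable":
        """Build from an iterable of (id, cell_type, abundance) triples."""
        return cls(pd.DataFrame(records, columns=["id", "cell_type", "abundance"]))

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.df["cell_type"].unique())

    def abundances(self, cell_type: str) -> dict[str, float]:
        """Mapping canonical id key -> abundance for one cell type."""
        sub = self.df[self.df["cell_type"] == cell_type]
        return dict(zip(sub["_key"], sub["abundance"]))

    def to_tsv(self, path: str | Path) -> None:
        self.df[["id", "cell_type", "abundance"]].to_csv(path, sep="\t", index=False)


def filter_by_expression(
    network: SignalingNetwork,
    table: ExpressionTable,
    cell_type: str,
    threshold: float = DEFAULT_THRESHOLD,
    keep_panel: MediatorPanel | None = None,
) -> SignalingNetwork:
    """Restrict a network to nodes expressed in ``cell_type``.

    A node is retained when its abundance in ``cell_type`` is strictly greater
    than ``threshold``; nodes absent from the table are dropped (counted and
    logged).  Panel mediators in ``keep_panel`` are always retained.  Edges
    incident to dropped nodes are removed and the result is revalidated.
    """
    if cell_type not in table.cell_types:
        raise ValueError(
            f"unknown cell type {cell_type!r}; table has {table.cell_types}"
        )
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    abund = table.abundances(cell_type)
    panel_keys = (
        {_key(p) for p in keep_panel.all_ids()} if keep_panel is not None else set()
    )

    kept, missing = set(), 0
    for node in network.nodes():
        k = _key(node.id)
        if k in panel_keys:
            kept.add(k)
            continue
        if k not in abund:
            missing += 1
            continue
        if abund[k] > threshold:
            kept.add(k)
    if missing:
        logger.info(
            "%s: %d node(s) absent from expression table for %r, dropped",
            network.name, missing, cell_type,
        )

    out = SignalingNetwork(f"{network.name}|{cell_type}")
    for node in network.nodes():
        if _key(node.id) in kept:
            out.add_node(node.id, node.role, node.provenance)
    for edge, prov in network.edges():
        if _key(edge.source) in kept and _key(edge.target) in kept:
            out.add_edge(edge.source, edge.target, edge.interaction, prov)
    out.meta["nodes_missing_from_table"] = missing
    out.validate()
    return out
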
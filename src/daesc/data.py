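"""Per-gene allele-specific count container and long-format TSV I/O.

The unit of analysis is one gene's per-cell allele-specific counts across
donors: for cell *j* of donor *i*, ``y`` alternative-haplotype reads out of
``n`` total allele-specific reads, plus a cell-level covariate ``x`` (cell
state, pseudotime, or a donor-constant condition such as disease status).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["gene", "donor", "cell", "alt_count", "total_count", "x"]


@dataclass
class GeneASECounts:
    """Allele-specific read counts for one gene across cells and donors.

    Parameters
    ----------
    gene_id : str
        Gene identifier.
    donor_id : ndarray of object/str, length C
        Donor label per cell.
    y : ndarray of int, length C
        Alternative-haplotype read count per cell.
    n : ndarray of int, length C
        Total allele-specific read count per cell (strictly positive;
        zero-total cells are dropped at construction).
    x : ndarray of float, length C
        Cell-level covariate.
    cell_id : ndarray, optional
        Cell identifiers; synthesized if absent.
    """

    gene_id: str
    donor_id: np.ndarray
    y: np.ndarray
    n: np.ndarray
    x: np.ndarray
    cell_id: np.ndarray | None = None
    # derived, filled in __post_init__
    donors: np.ndarray = field(init=False, repr=False)
    donor_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.donor_id = np.asarray(self.donor_id)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        lengths = {len(self.donor_id), len(self.y), len(self.n), len(self.x)}
        if len(lengths) != 1:
            raise ValueError("donor_id, y, n, x must have equal length")
        if np.any(self.y < 0):
            raise ValueError("negative alternative counts")
        keep = self.n > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s: dropped %d cells with zero total count",
                        self.gene_id, n_dropped)
            self.donor_id = self.donor_id[keep]
            self.y = self.y[keep]
            self.n = self.n[keep]
            self.x = self.x[keep]
            if self.cell_id is not None:
                self.cell_id = np.asarray(self.cell_id)[keep]
        if np.any(self.y > self.n):
            raise ValueError("alternative count exceeds total count")
        if len(self.y) == 0:
            raise ValueError(f"{self.gene_id}: no cells with positive totals")
        if self.cell_id is None:
            self.cell_id = np.array([f"cell{i}" for i in range(len(self.y))])
        # stable donor encoding in order of first appearance
        donors, first = np.unique(self.donor_id, return_index=True)
        order = np.argsort(first)
        self.donors = donors[order]
        lookup = {d: i for i, d in enumerate(self.donors)}
        self.donor_index = np.array([lookup[d] for d in self.donor_id],
                                    dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return len(self.y)

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene_id: str | None = None
                       ) -> "GeneASECounts":
        """Build from a long-format frame with the standard columns.

        Expected columns: ``gene``, ``donor``, ``cell``, ``alt_count``,
        ``total_count``, ``x``. If ``gene_id`` is None the frame must
        contain exactly one gene.
        """
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if gene_id is None:
            genes = df["gene"].unique()
            if len(genes) != 1:
                raise ValueError("frame holds multiple genes; pass gene_id")
            gene_id = genes[0]
        else:
            df = df[df["gene"] == gene_id]
            if df.empty:
                raise ValueError(f"gene {gene_id!r} not present")
        return cls(
            gene_id=str(gene_id),
            donor_id=df["donor"].to_numpy(),
            y=df["alt_count"].to_numpy(),
            n=df["total_count"].to_numpy(),
            x=df["x"].to_numpy(),
            cell_id=df["cell"].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene_id,
            "donor": self.donor_id,
            "cell": self.cell_id,
            "alt_count": self.y,
            "total_count": self.n,
            "x": self.x,
        })

    def flip_alleles(self) -> "GeneASECounts":
        """Swap alternative/reference roles (y -> n - y)."""
        return GeneASECounts(self.gene_id, self.donor_id.copy(),
                             self.n - self.y, self.n.copy(), self.x.copy(),
                             cell_id=np.asarray(self.cell_id).copy())

    def pseudobulk_fraction(self) -> np.ndarray:
        """Per-donor pooled alternative fraction, mildly shrunk away from 0/1."""
        alt = np.bincount(self.donor_index, weights=self.y,
                          minlength=self.n_donors)
        tot = np.bincount(self.donor_index, weights=self.n,
                          minlength=self.n_donors)
        return (alt + 0.5) / (tot + 1.0)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a long-format counts TSV, validating the schema."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty input")
    bad = df.index[(df["alt_count"] < 0) | (df["alt_count"] > df["total_count"])]
    if len(bad):
        lines = (bad + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"{path}: invalid counts at lines {lines}")
    return df


def iter_genes(df: pd.DataFrame):
    """Yield GeneASECounts per gene, in sorted gene order."""
    for gene, sub in df.groupby("gene", sort=True):
        yield GeneASECounts.from_dataframe(sub, gene_id=gene)


def write_tsv(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a TSV with an optional versioned schema header comment."""
    with open(path, "w") as fh:
        if schema is not None:
            fh.write(f"# daesc-schema: {schema} v1\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
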
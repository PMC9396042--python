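"""Count-matrix / sample-sheet I/O and resolution of the 10-gene RSI panel.

The radiosensitivity index (RSI) is a fixed linear signature over ten genes.
The signature's published symbols (AR, cJun, ...) are not gene identifiers,
so a configurable alias table maps each symbol to the HGNC symbols (or
Ensembl ids) that may appear in a count matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CountMatrixError, PanelError, SampleSheetError

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "PanelDefinition",
    "RSI_COEFFICIENTS",
    "DEFAULT_ALIASES",
    "default_panel",
    "load_panel_yaml",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "resolve_panel",
]

#: Signature coefficients, in the fixed published order of the linear form.
RSI_COEFFICIENTS: dict[str, float] = {
    "AR": -0.0098009,
    "cJun": 0.0128283,
    "STAT1": 0.0254552,
    "PKC": -0.0017589,
    "RelA": -0.0038171,
    "cABL": 0.1070213,
    "SUMO1": -0.0002509,
    "CDK1": -0.0092431,
    "HDAC1": -0.0204469,
    "IRF1": -0.0441683,
}

#: Default mapping from signature symbol to accepted gene identifiers.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "AR": ("AR",),
    "cJun": ("JUN",),
    "STAT1": ("STAT1",),
    "PKC": ("PRKCB", "PRKCB1"),
    "RelA": ("RELA",),
    "cABL": ("ABL1",),
    "SUMO1": ("SUMO1",),
    "CDK1": ("CDK1", "CDC2"),
    "HDAC1": ("HDAC1",),
    "IRF1": ("IRF1",),
}

_ENSEMBL_VERSION = re.compile(r"\.\d+$")


def _strip_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix (e.g. ``ENSG...123.7``)."""
    return _ENSEMBL_VERSION.sub("", gene_id)


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer gene x sample counts.

    Attributes
    ----------
    counts:
        Integer DataFrame, genes in rows (index = gene ids), samples in
        columns. All cells are non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise CountMatrixError(f"duplicate gene id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise CountMatrixError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            g, s = map(int, np.argwhere(arr < 0)[0])
            raise CountMatrixError(
                f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample column sums of the raw counts."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: one row per sample, tissue is tumor/normal."""

    table: pd.DataFrame  # columns: sample_id, patient_id, tissue

    TISSUES = ("tumor", "normal")

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise SampleSheetError(f"sample sheet missing columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()].iloc[0]
            raise SampleSheetError(f"duplicated sample_id {dup!r}")
        bad = set(self.table["tissue"]) - set(self.TISSUES)
        if bad:
            raise SampleSheetError(
                f"unknown tissue label(s) {sorted(bad)}; expected one of {self.TISSUES}"
            )

    def samples(self, tissue: str | None = None) -> list[str]:
        t = self.table
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return list(t["sample_id"])

    def tissue_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise SampleSheetError(f"unknown sample_id {sample_id!r}")
        return row["tissue"].iloc[0]

    def patient_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise SampleSheetError(f"unknown sample_id {sample_id!r}")
        return row["patient_id"].iloc[0]


@dataclass(frozen=True)
class PanelDefinition:
    """The ten signature genes: coefficients plus an identifier alias table."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(RSI_COEFFICIENTS)
    )
    aliases: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ALIASES.items()}
    )

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(RSI_COEFFICIENTS):
            raise PanelError(
                "panel must define coefficients for exactly the ten signature genes"
            )
        for name in self.coefficients:
            if not self.aliases.get(name):
                raise PanelError(f"no alias defined for panel gene {name!r}")

    @property
    def canonical_names(self) -> list[str]:
        """Signature symbols in the fixed order of the published linear form."""
        return list(RSI_COEFFICIENTS)


def default_panel() -> PanelDefinition:
    return PanelDefinition()


def load_panel_yaml(path: str | Path) -> PanelDefinition:
    """Load an alias override (YAML: canonical name -> list of identifiers).

    Names absent from the file keep their default aliases.
    """
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    unknown = set(override) - set(RSI_COEFFICIENTS)
    if unknown:
        raise PanelError(f"unknown panel gene(s) in alias file: {sorted(unknown)}")
    aliases = {k: tuple(v) for k, v in DEFAULT_ALIASES.items()}
    for name, ids in override.items():
        if isinstance(ids, str):
            ids = [ids]
        aliases[name] = tuple(ids)
    return PanelDefinition(aliases=aliases)


def read_counts(path: str | Path, allow_fractional: bool = False) -> CountMatrix:
    """Read a tab-delimited count matrix (first column gene ids, header samples).

    Parameters
    ----------
    allow_fractional:
        If true, fractional counts (as emitted by estimated-count
        quantifiers) are rounded half-to-even; otherwise they are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise CountMatrixError(f"{path}: no genes (empty file)") from None
    if df.shape[0] == 0:
        raise CountMatrixError(f"{path}: no genes")
    if df.shape[1] == 0:
        raise CountMatrixError(f"{path}: malformed header (no sample columns)")
    df.index = df.index.astype(str)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        g, s = map(int, np.argwhere(mask)[0])
        raise CountMatrixError(
            f"{path}: non-numeric value {df.iat[g, s]!r} at "
            f"gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    arr = numeric.to_numpy(dtype=float)
    if (arr < 0).any():
        g, s = map(int, np.argwhere(arr < 0)[0])
        raise CountMatrixError(
            f"{path}: negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    frac = arr != np.floor(arr)
    if frac.any():
        if not allow_fractional:
            g, s = map(int, np.argwhere(frac)[0])
            raise CountMatrixError(
                f"{path}: fractional count {arr[g, s]} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r} (pass allow_fractional to round)"
            )
        arr = np.rint(arr)  # round half to even
    counts = pd.DataFrame(
        arr.astype(np.int64), index=numeric.index, columns=numeric.columns
    )
    return CountMatrix(counts)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV; round-trips bit-exactly through read_counts."""
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path, cm: CountMatrix) -> SampleSheet:
    """Read a sample sheet CSV and validate it against a count matrix.

    Rows are reordered to the count matrix's sample order.
    """
    df = pd.read_csv(path, dtype=str)
    sheet_ids = list(df.get("sample_id", []))
    unknown = set(sheet_ids) - set(cm.sample_ids)
    if unknown:
        raise SampleSheetError(
            f"sample sheet references sample(s) absent from counts: {sorted(unknown)}"
        )
    missing = set(cm.sample_ids) - set(sheet_ids)
    if missing:
        raise SampleSheetError(
            f"count matrix sample(s) missing from sheet: {sorted(missing)}"
        )
    sheet = SampleSheet(df)  # validates columns, duplicates, tissue labels
    ordered = sheet.table.set_index("sample_id").loc[cm.sample_ids].reset_index()
    return SampleSheet(ordered)


def resolve_panel(
    cm: CountMatrix, panel: PanelDefinition | None = None
) -> dict[str, int]:
    """Map each signature symbol to exactly one gene row index.

    Matching is case-sensitive on the gene identifier after stripping a
    trailing Ensembl version suffix. Zero matches or multiple matches for a
    symbol are errors — there is no silent pick.
    """
    panel = panel or default_panel()
    stripped = [_strip_version(g) for g in cm.gene_ids]
    mapping: dict[str, int] = {}
    for name in panel.canonical_names:
        accepted = set(panel.aliases[name])
        hits = [i for i, g in enumerate(stripped) if g in accepted]
        if not hits:
            raise PanelError(
                f"panel gene missing: {name} (accepted ids: {sorted(accepted)})"
            )
        if len(hits) > 1:
            ids = [cm.gene_ids[i] for i in hits]
            raise PanelError(f"panel gene {name} is ambiguous: matches rows {ids}")
        mapping[name] = hits[0]
    return mapping
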
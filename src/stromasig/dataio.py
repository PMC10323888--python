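"""Core containers and file I/O.

The pipeline's universal substrate is a log-scale gene × sample expression
matrix.  This module provides a validated container for it plus readers and
writers for the plain-text formats the pipeline touches: delimited expression
matrices (TSV/CSV), survival tables (CSV), gene sets (Broad GMT dialect) and
probe→gene maps.  Gene identifiers are harmonized (stripped, uppercased)
at every entry point so that cross-cohort set operations are not defeated by
symbol-case drift between array platforms.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stromasig")

__all__ = [
    "FormatError",
    "ParseError",
    "ExpressionMatrix",
    "GeneSet",
    "ProbeMap",
    "SurvivalTable",
    "harmonize_gene_id",
    "read_expression",
    "write_expression",
    "collapse_probes",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "read_survival",
    "write_survival",
    "load_packaged_signatures",
    "packaged_data_path",
    "configure_logging",
]


class FormatError(ValueError):
    """Structural problem in an input file (missing header, bad field count)."""


class ParseError(ValueError):
    """A cell failed to parse; message carries row/column coordinates."""


def configure_logging(level: str = "INFO") -> None:
    """Timestamped logging to stderr for the CLI and scripts."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


def harmonize_gene_id(gene_id: str) -> str:
    """Strip whitespace and uppercase a gene identifier."""
    return str(gene_id).strip().upper()


class ExpressionMatrix:
    """Log-scale gene × sample expression matrix.

    Parameters
    ----------
    data
        DataFrame with genes as index and samples as columns.  Values are
        log-scale intensities or log-CPM (unitless).
    harmonize
        Uppercase/strip gene identifiers on construction (default True).

    Invariants enforced: unique gene ids, unique sample ids, all values
    finite.
    """

    def __init__(self, data: pd.DataFrame, *, harmonize: bool = True) -> None:
        df = data.copy()
        if harmonize:
            df.index = [harmonize_gene_id(g) for g in df.index]
        else:
            df.index = [str(g) for g in df.index]
        df.columns = [str(c).strip() for c in df.columns]
        dup_genes = df.index[df.index.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicate gene ids: {', '.join(map(str, dup_genes[:5]))}")
        dup_samples = pd.Index(df.columns)[pd.Index(df.columns).duplicated()].unique()
        if len(dup_samples):
            raise ValueError(
                f"duplicate sample ids: {', '.join(map(str, dup_samples[:5]))}"
            )
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.data = df.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given genes (harmonized; order = given order)."""
        wanted = [harmonize_gene_id(g) for g in genes]
        present = [g for g in wanted if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present], harmonize=False)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)], harmonize=False)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (harmonized, non-empty, unique)."""

    name: str
    description: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        harmonized = frozenset(harmonize_gene_id(g) for g in self.genes if str(g).strip())
        object.__setattr__(self, "genes", harmonized)

    @property
    def genes_sorted(self) -> list[str]:
        """Deterministic (lexicographic) gene order."""
        return sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return harmonize_gene_id(gene) in self.genes


# A signature is just a gene set produced by a derivation step; the alias
# keeps call sites self-documenting.
SignatureGeneSet = GeneSet


@dataclass(frozen=True)
class ProbeMap:
    """Many-to-one probe → gene mapping."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for probe, gene in self.mapping.items():
            gene_h = harmonize_gene_id(gene)
            if not gene_h:
                raise ValueError(f"probe {probe!r} maps to an empty gene id")
            clean[str(probe).strip()] = gene_h
        object.__setattr__(self, "mapping", clean)

    def __getitem__(self, probe: str) -> str:
        return self.mapping[str(probe).strip()]

    def __contains__(self, probe: str) -> bool:
        return str(probe).strip() in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


class SurvivalTable:
    """Per-sample overall survival: time (months), event flag, covariates.

    ``event`` is 1 for death, 0 for censoring at last follow-up.  Any extra
    columns travel along verbatim as covariates.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        df = data.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {', '.join(dups[:5])}")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing required column {col!r}")
        times = pd.to_numeric(df["time"], errors="raise")
        if (times < 0).any():
            raise ValueError("negative survival times")
        events = pd.to_numeric(df["event"], errors="raise")
        if not events.isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")
        df["time"] = times.astype(float)
        df["event"] = events.astype(int)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SurvivalTable({self.n} samples, {int(self.event.sum())} events)"


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    probe_map: ProbeMap | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The first column holds row identifiers and a header row is required.
    With ``orientation="samples_in_rows"`` the parsed table is transposed.
    Duplicate gene rows are only legal when ``probe_map`` is supplied, in
    which case rows are treated as probes and collapsed to gene level by
    per-gene averaging (see :func:`collapse_probes`).

    Rows containing missing values are dropped (logged); they cannot enter a
    correlation screen and imputation is out of contract.
    """
    path = Path(path)
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    if raw.columns.size == 0:
        raise FormatError(f"{path}: no data columns (missing header?)")
    # A header whose fields all parse as numbers is almost certainly data.
    numeric_header = all(_is_number(c) for c in raw.columns)
    if numeric_header:
        raise FormatError(f"{path}: header row looks numeric; expected sample ids")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    df = numeric
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d rows with missing values from %s", n_missing, path)
        df = df.dropna(axis=0)

    if probe_map is not None:
        probe_level = ExpressionMatrix._from_probe_frame(df)
        return collapse_probes(probe_level, probe_map)

    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(
            f"{path}: duplicate row ids without a probe map: "
            f"{', '.join(map(str, dup[:5]))}"
        )
    return ExpressionMatrix(df)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


class _ProbeFrame:
    """Internal: a probe-level matrix that tolerates duplicate row ids."""

    def __init__(self, data: pd.DataFrame) -> None:
        self.data = data.astype(float)


# helper used by read_expression when a probe map is supplied
ExpressionMatrix._from_probe_frame = staticmethod(_ProbeFrame)  # type: ignore[attr-defined]


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    out = matrix.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def collapse_probes(
    matrix: ExpressionMatrix | _ProbeFrame, probe_map: ProbeMap
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Each gene row is the arithmetic mean of its probe rows, per sample.
    Probes absent from the map are dropped with a logged count; mapping
    nothing at all is an error.
    """
    df = matrix.data
    mapped_mask = np.array([p in probe_map for p in df.index])
    n_dropped = int((~mapped_mask).sum())
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_dropped)
    kept = df.loc[mapped_mask]
    if kept.empty:
        raise ValueError("collapse_probes: no probe mapped to a gene")
    genes = [probe_map[p] for p in kept.index]
    collapsed = kept.groupby(pd.Index(genes, name="gene_id"), sort=True).mean()
    return ExpressionMatrix(collapsed, harmonize=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a Broad-dialect GMT file (one set per line:
    name <tab> description <tab> gene1 <tab> ... geneN)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, description=description, genes=frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes_sorted]) + "\n")


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a two-column (probe_id, gene_id) delimited file with header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    return ProbeMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


# ---------------------------------------------------------------------------
# Survival CSV
# ---------------------------------------------------------------------------

_SURV_REQUIRED = ("sample_id", "os_months", "os_event")


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival CSV with required columns sample_id, os_months,
    os_event; every additional column becomes a covariate verbatim."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _SURV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    df = df.rename(columns={"os_months": "time", "os_event": "event"})
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    out = table.data.rename(columns={"time": "os_months", "event": "os_event"})
    out = out.reset_index().rename(columns={"index": "sample_id"})
    # keep the canonical column order
    cols = ["sample_id", "os_months", "os_event"] + [
        c for c in out.columns if c not in ("sample_id", "os_months", "os_event")
    ]
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def packaged_data_path(filename: str) -> Path:
    """Path to a data file shipped inside the package."""
    return Path(str(resources.files("stromasig").joinpath("data", filename)))


def load_packaged_signatures() -> dict[str, GeneSet]:
    """The two fixed stromal signatures shipped with the package.

    ``SALL4_CORRELATED_24`` — the 24 genes positively correlated with the
    anchor gene SALL4 in all three discovery cohorts.
    ``SALL4_INVASIVE_7`` — the subset of 7 genes additionally up-regulated
    in invasive carcinoma versus both pre-invasive (PanIN) lesions and
    normal pancreas.
    """
    sets = read_gmt(packaged_data_path("sall4_signatures.gmt"))
    return {gs.name: gs for gs in sets}
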
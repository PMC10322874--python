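"""Reading, validation and writing of the flat annotation-table formats.

The pipeline consumes three tab-separated inputs:

* a **gene table** — one row per predicted ORF, with gene length, an optional
  ranked lineage, CAZyme family labels, an optional transporter KO id, an
  optional secretion flag, and one integer read-count column per sample;
* a **sample metadata table** — size fraction (FL / PA / sediment), layer,
  station and library size per sample;
* curated **mapping tables** — CAZyme family → substrate category, and
  KEGG KO → transporter class. Default versions of both ship with the
  package and load without a path.

Multi-valued cells (several CAZyme families on one gene, ranked lineages) use
``;`` as the delimiter. Lineages are rank-prefixed
(``d__Bacteria;p__Proteobacteria;...;g__Alteromonas``) and may terminate
early at any rank.

Parsing never drops rows silently: every rejection raises with the offending
row number, and accepted row counts are logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: CAZy enzyme-class prefixes.
CAZYME_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

#: Degradative classes — everything except the biosynthetic GTs.
DEGRADATIVE_CLASSES = frozenset({"GH", "PL", "CE", "AA", "CBM"})

_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)$")

#: Controlled vocabulary of substrate categories.
SUBSTRATE_VOCAB = frozenset(
    {
        "alpha_glucan",
        "beta_glucan",
        "N_glycan",
        "cellulose_hemicellulose",
        "beta_mannoside",
        "lignin",
        "fucose_SP",
        "rhamnose_SP",
        "pectin",
        "alginate",
    }
)

#: Transporter class vocabulary.
TRANSPORTER_CLASSES = ("ABC", "PTS", "MFS", "TonB", "SusC")

#: Supported taxonomic ranks, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_RANK_PREFIXES = {"d": "domain", "p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}

FRACTIONS = ("FL", "PA", "sediment")
LAYERS = ("surface", "bottom", "sediment")

_GENE_FIXED_COLUMNS = (
    "gene_id",
    "contig_id",
    "length_bp",
    "contig_bp",
    "lineage",
    "cazyme_families",
    "ko_id",
    "secreted",
)
_GENE_REQUIRED_COLUMNS = ("gene_id", "length_bp")


class TableFormatError(ValueError):
    """A file does not conform to the documented TSV contract."""


class ValidationError(ValueError):
    """A row violates a declared invariant."""


# ---------------------------------------------------------------------------
# lineages
# ---------------------------------------------------------------------------

def parse_lineage(text: object) -> tuple[str, ...]:
    """Parse a semicolon-delimited rank-prefixed lineage string.

    Returns a tuple of tokens such as ``("d__Bacteria", "p__Proteobacteria")``.
    Empty / missing values yield an empty tuple (an unclassified gene).
    Unranked tails (tokens without a recognised prefix) are permitted and kept
    verbatim.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ()
    s = str(text).strip()
    if not s or s.lower() in {"na", "nan", "unclassified"}:
        return ()
    return tuple(tok.strip() for tok in s.split(";") if tok.strip())


def format_lineage(lineage: Iterable[str]) -> str:
    toks = tuple(lineage)
    return ";".join(toks) if toks else "unclassified"


def lineage_at_rank(lineage: Iterable[str], rank: str) -> Optional[str]:
    """Return the name at *rank* (e.g. ``"Alteromonas"`` for genus), or None.

    Tokens are matched by their single-letter prefix; an unranked tail is
    matched positionally as a fallback.
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}; choose one of {RANKS}")
    toks = tuple(lineage)
    prefix = rank[0] + "__"
    for tok in toks:
        if tok.startswith(prefix):
            name = tok[len(prefix):]
            return name or None
    # positional fallback for unprefixed lineages
    idx = RANKS.index(rank)
    if toks and idx < len(toks) and "__" not in toks[idx]:
        return toks[idx]
    return None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata; ``total_reads`` is the library size used as the
    RPKM denominator ("number of reads in sample")."""

    sample_id: str
    fraction: str
    layer: str
    station: str
    total_reads: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: fraction {self.fraction!r} not in {FRACTIONS}"
            )
        if self.layer not in LAYERS:
            raise ValidationError(
                f"sample {self.sample_id!r}: layer {self.layer!r} not in {LAYERS}"
            )
        if (self.fraction == "sediment") != (self.layer == "sediment"):
            raise ValidationError(
                f"sample {self.sample_id!r}: fraction=sediment iff layer=sediment"
            )
        if self.total_reads < 1:
            raise ValidationError(f"sample {self.sample_id!r}: total_reads must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated ORF with read counts, taxonomy and functional labels."""

    gene_id: str
    contig_id: str
    length_bp: int
    reads_mapped: Mapping[str, int]
    lineage: tuple[str, ...] = ()
    cazyme_families: frozenset[str] = frozenset()
    ko_id: Optional[str] = None
    secreted: Optional[bool] = None
    #: Length of the carrying contig; defaults to the gene length (a gene
    #: cannot be longer than its contig), used by the >500 bp contig filter.
    contig_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValidationError(f"gene {self.gene_id!r}: length_bp must be >= 1")
        for fam in self.cazyme_families:
            if not _FAMILY_RE.match(fam):
                raise ValidationError(
                    f"gene {self.gene_id!r}: CAZyme family label {fam!r} does not match "
                    f"class prefix in {CAZYME_CLASSES} followed by digits"
                )
        for sid, n in self.reads_mapped.items():
            if n < 0:
                raise ValidationError(
                    f"gene {self.gene_id!r}: negative read count for sample {sid!r}"
                )

    @property
    def effective_contig_bp(self) -> int:
        return self.contig_bp if self.contig_bp is not None else self.length_bp

    @property
    def cazyme_classes(self) -> frozenset[str]:
        return frozenset(_FAMILY_RE.match(f).group(1) for f in self.cazyme_families)


def family_class(family: str) -> str:
    """Enzyme-class prefix of a family label (``"GH13"`` -> ``"GH"``)."""
    m = _FAMILY_RE.match(family)
    if not m:
        raise ValidationError(f"malformed CAZyme family label {family!r}")
    return m.group(1)


@dataclass(frozen=True)
class SubstrateMap:
    """CAZyme family → set of substrate-category labels.

    Families absent from the map are reported as ``"unmapped"`` by the
    aggregation step, never silently dropped.
    """

    mapping: Mapping[str, frozenset[str]]
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, cats in self.mapping.items():
            bad = set(cats) - SUBSTRATE_VOCAB
            if bad:
                raise ValidationError(
                    f"substrate map: family {fam!r} has labels {sorted(bad)} outside the "
                    f"controlled vocabulary {sorted(SUBSTRATE_VOCAB)}"
                )

    def categories(self, family: str) -> frozenset[str]:
        return self.mapping.get(family, frozenset())

    def __contains__(self, family: str) -> bool:
        return family in self.mapping

    @classmethod
    def default(cls) -> "SubstrateMap":
        """Bundled map curated from published family–substrate designations."""
        with resources.files("glyconiche.data").joinpath("substrate_map.tsv").open() as fh:
            return read_substrate_map(fh)


@dataclass(frozen=True)
class TransporterKOMap:
    """KEGG KO → transporter class in {ABC, PTS, MFS, TonB, SusC}."""

    class_of: Mapping[str, str]
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ko, cls_ in self.class_of.items():
            if cls_ not in TRANSPORTER_CLASSES:
                raise ValidationError(
                    f"transporter map: KO {ko!r} has class {cls_!r} outside "
                    f"{TRANSPORTER_CLASSES}"
                )

    def __contains__(self, ko: str) -> bool:
        return ko in self.class_of

    def __getitem__(self, ko: str) -> str:
        return self.class_of[ko]

    @classmethod
    def default(cls) -> "TransporterKOMap":
        """Bundled map of the sugar-transporter KOs used in the study design."""
        with resources.files("glyconiche.data").joinpath("transporter_ko_map.tsv").open() as fh:
            return read_transporter_map(fh)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sample_metadata(path) -> dict[str, SampleMeta]:
    """Read the sample metadata TSV into an ordered ``sample_id -> SampleMeta``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("sample_id", "fraction", "layer", "station", "total_reads")
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"sample metadata is missing required column {col!r}")
    out: dict[str, SampleMeta] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.sample_id)
        if sid in out:
            raise ValidationError(f"duplicate sample_id {sid!r} at metadata row {i}")
        try:
            total = int(row.total_reads)
        except (TypeError, ValueError):
            raise ValidationError(f"metadata row {i}: total_reads {row.total_reads!r} is not an integer")
        out[sid] = SampleMeta(sid, str(row.fraction), str(row.layer), str(row.station), total)
    return out


def _parse_secreted(value: object) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in {"", "na", "nan", "none"}:
        return None
    if s in {"1", "true", "yes", "y", "secreted"}:
        return True
    if s in {"0", "false", "no", "n", "cytoplasmic", "membrane"}:
        return False
    raise ValidationError(f"unrecognised secreted flag {value!r}")


def read_gene_table(path, samples: Mapping[str, SampleMeta]) -> list[GeneRecord]:
    """Read and validate a gene annotation table.

    Every column that is not one of the fixed annotation columns must be a
    declared sample id (its values are mapped read counts). Raises
    :class:`TableFormatError` for structural problems and
    :class:`ValidationError` (citing the 1-based data row) for bad values.
    Logs a parse report: rows read, rows with CAZyme labels, rows with KO ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _GENE_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"gene table is missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in _GENE_FIXED_COLUMNS]
    unknown = [c for c in sample_cols if c not in samples]
    if unknown:
        raise TableFormatError(
            f"gene table has unknown sample column(s) {unknown}; declared samples are "
            f"{sorted(samples)}"
        )
    if not sample_cols:
        raise TableFormatError("gene table has no per-sample read-count columns")

    records: list[GeneRecord] = []
    n_caz = n_ko = 0
    max_reads = {sid: 0 for sid in sample_cols}
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            length_bp = int(row["length_bp"])
        except (TypeError, ValueError):
            raise ValidationError(f"row {i}: length_bp {row['length_bp']!r} is not an integer")
        if length_bp < 1:
            raise ValidationError(f"row {i}: length_bp must be >= 1, got {length_bp}")
        contig_bp: Optional[int] = None
        if "contig_bp" in row and not _is_missing(row.get("contig_bp")):
            contig_bp = int(row["contig_bp"])
            if contig_bp < 1:
                raise ValidationError(f"row {i}: contig_bp must be >= 1, got {contig_bp}")
        reads: dict[str, int] = {}
        for sid in sample_cols:
            try:
                n = int(row[sid])
            except (TypeError, ValueError):
                raise ValidationError(f"row {i}: read count {row[sid]!r} in column {sid!r} is not an integer")
            if n < 0:
                raise ValidationError(f"row {i}: negative read count {n} in column {sid!r}")
            reads[sid] = n
            max_reads[sid] = max(max_reads[sid], n)
        fams = _parse_families(row.get("cazyme_families"))
        ko = None if _is_missing(row.get("ko_id")) else str(row["ko_id"]).strip() or None
        try:
            rec = GeneRecord(
                gene_id=str(row["gene_id"]),
                contig_id=str(row.get("contig_id", "")) if not _is_missing(row.get("contig_id")) else "",
                length_bp=length_bp,
                reads_mapped=reads,
                lineage=parse_lineage(row.get("lineage")),
                cazyme_families=fams,
                ko_id=ko,
                secreted=_parse_secreted(row.get("secreted")),
                contig_bp=contig_bp,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        if rec.cazyme_families:
            n_caz += 1
        if rec.ko_id:
            n_ko += 1
        records.append(rec)

    for sid in sample_cols:
        if max_reads[sid] > samples[sid].total_reads:
            raise ValidationError(
                f"sample {sid!r}: a gene has {max_reads[sid]} mapped reads, exceeding the "
                f"declared library size {samples[sid].total_reads}"
            )
    logger.info(
        "read_gene_table: %d rows read, %d with CAZyme labels, %d with KO labels (%d samples)",
        len(records), n_caz, n_ko, len(sample_cols),
    )
    return records


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip() == ""


def _parse_families(value: object) -> frozenset[str]:
    if _is_missing(value):
        return frozenset()
    return frozenset(tok.strip() for tok in str(value).split(";") if tok.strip())


def read_substrate_map(path_or_buf) -> SubstrateMap:
    """Read a family→category TSV; duplicate family rows merge into label sets."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError("substrate map needs at least two columns (family, category)")
    fam_col, cat_col = df.columns[0], df.columns[1]
    mapping: dict[str, set[str]] = {}
    notes: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        fam = str(getattr(row, fam_col, row[0])).strip()
        cat = str(row[1]).strip()
        if cat not in SUBSTRATE_VOCAB:
            raise ValidationError(
                f"substrate map row {i}: category {cat!r} is outside the controlled "
                f"vocabulary {sorted(SUBSTRATE_VOCAB)}"
            )
        mapping.setdefault(fam, set()).add(cat)
        if df.shape[1] > 2 and not _is_missing(row[2]):
            notes[fam] = str(row[2])
    return SubstrateMap({f: frozenset(c) for f, c in mapping.items()}, notes)


def read_transporter_map(path_or_buf) -> TransporterKOMap:
    """Read a KO→class TSV; duplicate KO rows are rejected."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError("transporter map needs at least two columns (ko_id, class)")
    class_of: dict[str, str] = {}
    notes: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ko = str(row[0]).strip()
        cls_ = str(row[1]).strip()
        if ko in class_of:
            raise ValidationError(f"transporter map row {i}: duplicate KO id {ko!r}")
        if cls_ not in TRANSPORTER_CLASSES:
            raise ValidationError(
                f"transporter map row {i}: class {cls_!r} is outside {TRANSPORTER_CLASSES}"
            )
        class_of[ko] = cls_
        if df.shape[1] > 2 and not _is_missing(row[2]):
            notes[ko] = str(row[2])
    return TransporterKOMap(class_of, notes)


def read_mapping_table(path=None, kind: str = "substrate"):
    """Read a curated mapping table; with ``path=None`` the bundled default loads."""
    if kind == "substrate":
        return SubstrateMap.default() if path is None else read_substrate_map(path)
    if kind == "transporter":
        return TransporterKOMap.default() if path is None else read_transporter_map(path)
    raise ValueError(f"unknown mapping kind {kind!r}; expected 'substrate' or 'transporter'")


# ---------------------------------------------------------------------------
# matrix writers
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path, layout: str = "full") -> None:
    """Write a labeled matrix as TSV.

    ``layout="full"`` writes the dense matrix at full float precision, so a
    round-trip with :func:`read_matrix` reproduces values to better than
    1e-12. ``layout="table1_style"`` writes the lower triangle of a symmetric
    overlap matrix with the diagonal rendered ``0.00`` — a display convention
    for printed overlap tables; the in-memory diagonal stays 1.
    """
    if layout == "full":
        matrix.to_csv(path, sep="\t", index_label="")
        return
    if layout == "table1_style":
        values = matrix.to_numpy(dtype=float)
        if values.shape[0] != values.shape[1] or not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("table1_style layout requires a square symmetric matrix")
        labels = list(matrix.index)
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
            for r, lab in enumerate(labels):
                cells = []
                for c in range(len(labels)):
                    if c > r:
                        cells.append("")
                    elif c == r:
                        cells.append("0.00")
                    else:
                        cells.append(f"{values[r, c]:.2f}")
                fh.write(str(lab) + "\t" + "\t".join(cells) + "\n")
        return
    raise ValueError(f"unknown layout {layout!r}; expected 'full' or 'table1_style'")


def read_matrix(path) -> pd.DataFrame:
    """Read a full-layout matrix TSV written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_table(genes: Iterable[GeneRecord], samples: Mapping[str, SampleMeta], path) -> None:
    """Serialize GeneRecords back to the gene-table TSV contract."""
    sample_ids = list(samples)
    rows = []
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "contig_id": g.contig_id,
            "length_bp": g.length_bp,
            "contig_bp": g.effective_contig_bp,
            "lineage": format_lineage(g.lineage) if g.lineage else "",
            "cazyme_families": ";".join(sorted(g.cazyme_families)),
            "ko_id": g.ko_id or "",
            "secreted": "" if g.secreted is None else int(g.secreted),
        }
        for sid in sample_ids:
            row[sid] = int(g.reads_mapped.get(sid, 0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sample_metadata(samples: Mapping[str, SampleMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "fraction": s.fraction,
                "layer": s.layer,
                "station": s.station,
                "total_reads": s.total_reads,
            }
            for s in samples.values()
        ]
    ).to_csv(path, sep="\t", index=False)
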
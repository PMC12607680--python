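"""Domain types and readers/writers for every external format the pipeline touches.

Formats: differential-expression TSV, TRANSFAC-style matrix flat file,
promoter FASTA, network edge/node TSVs, drug-target TSV and
compound-activity TSVs.  Readers validate strictly and never silently drop
rows; every writer emits a commented provenance header that readers skip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import report_header

logger = logging.getLogger(__name__)

PROMOTER_LEN = 1100
PROMOTER_START_OFFSET = -1000
PROMOTER_END_OFFSET = 100

VALID_LAYERS = ("transcriptome", "proteome")
VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DiffTable:
    """Differential features for one omics layer: feature_id, log_fc, p_value."""

    layer: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        required = {"feature_id", "log_fc", "p_value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"DiffTable missing columns: {sorted(missing)}")
        f = self.frame
        if f["feature_id"].isna().any() or (f["feature_id"].astype(str) == "").any():
            raise FormatError("empty feature_id")
        if f["feature_id"].duplicated().any():
            dups = f.loc[f["feature_id"].duplicated(), "feature_id"].tolist()
            raise FormatError(f"duplicate feature_id values: {dups[:5]}")
        if not np.isfinite(f["log_fc"].to_numpy(dtype=float)).all():
            raise FormatError("non-finite log_fc")
        p = f["p_value"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
            bad = f.loc[(f["p_value"] < 0) | (f["p_value"] > 1) | f["p_value"].isna()]
            raise FormatError(f"p_value outside [0,1] for: {bad['feature_id'].tolist()[:5]}")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_ids(self) -> list[str]:
        return self.frame["feature_id"].tolist()

    def lookup(self, feature_id: str) -> tuple[float, float] | None:
        """Return (log_fc, p_value) for a feature, or None when absent."""
        sub = self.frame[self.frame["feature_id"] == feature_id]
        if sub.empty:
            return None
        row = sub.iloc[0]
        return float(row["log_fc"]), float(row["p_value"])


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str
    label: str  # 'yes' | 'no'


@dataclass
class PromoterSet:
    """Fixed-width promoter sequences partitioned into Yes and No subsets."""

    records: list[PromoterRecord]
    start_offset: int = PROMOTER_START_OFFSET
    end_offset: int = PROMOTER_END_OFFSET

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.label not in ("yes", "no"):
                raise FormatError(f"{rec.gene_id}: label must be yes/no, got {rec.label!r}")
            if len(rec.sequence) != PROMOTER_LEN:
                raise FormatError(
                    f"{rec.gene_id}: sequence length {len(rec.sequence)} != {PROMOTER_LEN}"
                )
            if not set(rec.sequence) <= VALID_BASES:
                bad = sorted(set(rec.sequence) - VALID_BASES)
                raise FormatError(f"{rec.gene_id}: invalid characters {bad}")
            if rec.gene_id in seen:
                raise FormatError(f"duplicate promoter id {rec.gene_id}")
            seen.add(rec.gene_id)

    def subset(self, label: str) -> list[PromoterRecord]:
        return [r for r in self.records if r.label == label]

    @property
    def yes_records(self) -> list[PromoterRecord]:
        return self.subset("yes")

    @property
    def no_records(self) -> list[PromoterRecord]:
        return self.subset("no")

    def require_nonempty_split(self) -> None:
        if not self.yes_records or not self.no_records:
            raise FormatError("enrichment requires non-empty Yes and No subsets")


@dataclass
class PWMatrix:
    """Position weight matrix over A,C,G,T with a normalised-score cutoff."""

    matrix_id: str
    tf_symbols: tuple[str, ...]
    counts: np.ndarray  # shape (L, 4)
    cutoff: float = 0.85

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise FormatError(f"{self.matrix_id}: counts must be L x 4")
        if self.counts.shape[0] < 4:
            raise FormatError(f"{self.matrix_id}: matrix length must be >= 4")
        if (self.counts < 0).any():
            raise FormatError(f"{self.matrix_id}: negative counts")
        if (self.counts.sum(axis=1) <= 0).any():
            raise FormatError(f"{self.matrix_id}: position with no positive entry")
        if not 0.0 <= self.cutoff <= 1.0:
            raise FormatError(f"{self.matrix_id}: cutoff {self.cutoff} outside [0,1]")
        self.tf_symbols = tuple(self.tf_symbols)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True)
class NodeAnnotation:
    gene_symbols: tuple[str, ...] = ()
    is_transcription_factor: bool = False


@dataclass
class NetworkEdgeList:
    """Directed molecule graph; every edge endpoint carries an annotation."""

    edges: list[tuple[str, str, str]]
    node_annotations: dict[str, NodeAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = []
        n_loops = 0
        for src, tgt, lab in self.edges:
            if src == tgt:
                n_loops += 1
                continue
            cleaned.append((src, tgt, lab))
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        self.edges = cleaned
        for src, tgt, _ in self.edges:
            for node in (src, tgt):
                if node not in self.node_annotations:
                    self.node_annotations[node] = NodeAnnotation()

    @property
    def nodes(self) -> list[str]:
        return list(self.node_annotations)

    def tf_nodes(self) -> list[str]:
        return [n for n, a in self.node_annotations.items() if a.is_transcription_factor]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_annotations)
        for src, tgt, lab in self.edges:
            g.add_edge(src, tgt, label=lab)
        return g


@dataclass
class DrugTargetTable:
    """Curated compound -> target -> disease rows with max trial phase."""

    frame: pd.DataFrame  # compound_id, target_gene, disease_id, max_trial_phase

    def __post_init__(self) -> None:
        required = {"compound_id", "target_gene", "disease_id", "max_trial_phase"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"DrugTargetTable missing columns: {sorted(missing)}")
        phases = self.frame["max_trial_phase"].to_numpy()
        if not np.isin(phases, [0, 1, 2, 3, 4]).all():
            raise FormatError("max_trial_phase must be in {0,1,2,3,4}")
        key = self.frame[["compound_id", "target_gene", "disease_id"]]
        if key.duplicated().any():
            raise FormatError("duplicate (compound, target, disease) rows")
        self.frame = self.frame.reset_index(drop=True)

    def compounds(self) -> list[str]:
        return sorted(self.frame["compound_id"].unique())

    def targets_of(self, compound_id: str) -> set[str]:
        sub = self.frame[self.frame["compound_id"] == compound_id]
        return set(sub["target_gene"])


@dataclass
class CompoundActivityTable:
    """Predicted compound activities with Pa values plus per-gene weights.

    ``mapped_genes`` is a comma-joined gene list in the TSV and a tuple in
    memory.  ``iap`` and ``opt_weight`` are per-gene reliability/weight maps
    consumed by the predicted druggability formulas.
    """

    frame: pd.DataFrame  # compound_id, activity_name, activity_class, pa, mapped_genes
    iap: dict[str, float] = field(default_factory=dict)
    opt_weight: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"compound_id", "activity_name", "activity_class", "pa", "mapped_genes"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"CompoundActivityTable missing columns: {sorted(missing)}")
        pa = self.frame["pa"].to_numpy(dtype=float)
        if ((pa < 0) | (pa > 1)).any():
            raise FormatError("pa outside [0,1]")
        classes = set(self.frame["activity_class"])
        bad = classes - {"mechanism", "disease_effect", "toxicity"}
        if bad:
            raise FormatError(f"unknown activity_class values: {sorted(bad)}")
        self.frame = self.frame.copy()
        self.frame["mapped_genes"] = [
            tuple(g for g in (gs if isinstance(gs, (tuple, list)) else str(gs).split(","))
                  if g and g != "nan")
            for gs in self.frame["mapped_genes"]
        ]
        mech = self.frame[self.frame["activity_class"] == "mechanism"]
        if any(len(g) == 0 for g in mech["mapped_genes"]):
            raise FormatError("mechanism rows must map to at least one gene")
        for gene, v in list(self.iap.items()) + list(self.opt_weight.items()):
            if v < 0:
                raise FormatError(f"negative weight for gene {gene}")
        self.frame = self.frame.reset_index(drop=True)

    def compounds(self) -> list[str]:
        return sorted(self.frame["compound_id"].unique())

    def rows_for(self, compound_id: str) -> pd.DataFrame:
        return self.frame[self.frame["compound_id"] == compound_id]


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------


def read_diff_table(
    path: str | Path,
    layer: str,
    id_col: str = "id",
    lfc_col: str = "logFC",
    p_col: str = "p",
) -> DiffTable:
    """Read a tab-separated differential table.

    Duplicate feature IDs are collapsed by keeping the row with the smallest
    p-value (logged).  Missing columns raise :class:`FormatError` naming the
    column; non-numeric values raise with the offending line number.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (id_col, lfc_col, p_col):
        if col not in frame.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    n_parsed = len(frame)
    out = pd.DataFrame(
        {
            "feature_id": frame[id_col].astype(str),
            "log_fc": pd.to_numeric(frame[lfc_col], errors="coerce"),
            "p_value": pd.to_numeric(frame[p_col], errors="coerce"),
        }
    )
    bad = out["log_fc"].isna() | out["p_value"].isna()
    if bad.any():
        # +2: header line and 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(f"{path.name}: non-numeric logFC/p at line {line}")
    oob = (out["p_value"] < 0) | (out["p_value"] > 1)
    if oob.any():
        line = int(np.flatnonzero(oob.to_numpy())[0]) + 2
        raise FormatError(f"{path.name}: p outside [0,1] at line {line}")
    if out["feature_id"].duplicated().any():
        n_dup = int(out["feature_id"].duplicated().sum())
        logger.warning("%s: collapsing %d duplicate id(s), keeping min p", path.name, n_dup)
        out = out.sort_values(["p_value", "log_fc"], kind="stable")
        out = out.drop_duplicates("feature_id", keep="first")
        out = out.sort_index()
    logger.info("%s: parsed %d rows, kept %d, rejected 0", path.name, n_parsed, len(out))
    return DiffTable(layer=layer, frame=out.reset_index(drop=True))


def write_diff_table(
    table: DiffTable,
    path: str | Path,
    config_hash: str = "none",
    seed: int | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(report_header(config_hash, seed) + "\n")
        fh.write("id\tlogFC\tp\n")
        for row in table.frame.itertuples(index=False):
            fh.write(f"{row.feature_id}\t{row.log_fc:.10g}\t{row.p_value:.10g}\n")


# ---------------------------------------------------------------------------
# TRANSFAC-style matrix flat file
# ---------------------------------------------------------------------------


def read_pwm_library(path: str | Path, default_cutoff: float = 0.85) -> list[PWMatrix]:
    """Parse a TRANSFAC-style flat file of // delimited matrix blocks.

    Accepts both count matrices and pre-normalised frequency matrices (row
    sums near 1).  An unterminated final block is accepted with a log note.
    """
    path = Path(path)
    matrices: list[PWMatrix] = []
    matrix_id: str | None = None
    tf_symbols: list[str] = []
    rows: list[list[float]] = []
    terminated = True

    def flush() -> None:
        nonlocal matrix_id, tf_symbols, rows
        if matrix_id is None and not rows:
            return
        if matrix_id is None:
            raise FormatError(f"{path.name}: matrix block without ID line")
        if not rows:
            raise FormatError(f"{path.name}: block {matrix_id} has no matrix rows")
        matrices.append(
            PWMatrix(
                matrix_id=matrix_id,
                tf_symbols=tuple(tf_symbols),
                counts=np.array(rows, dtype=float),
                cutoff=default_cutoff,
            )
        )
        matrix_id, tf_symbols, rows = None, [], []

    for raw in path.read_text().splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("//"):
            flush()
            terminated = True
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "ID":
            matrix_id = rest
            terminated = False
        elif tag == "BF":
            tf_symbols.append(rest)
            terminated = False
        elif tag in ("P0", "PO", "NA", "DE", "XX", "CC", "AC"):
            continue  # header / metadata lines
        else:
            fields = line.split()
            # numbered row: "01  5 0 0 0" (position label then 4 values)
            if len(fields) == 5:
                values = fields[1:]
            elif len(fields) == 4:
                values = fields
            else:
                raise FormatError(
                    f"{path.name}: block {matrix_id or '?'}: matrix row needs 4 numeric "
                    f"fields, got {len(fields)}: {line!r}"
                )
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: block {matrix_id or '?'}: non-numeric row {line!r}"
                ) from exc
            terminated = False
    if not terminated:
        logger.warning("%s: final block missing // terminator, accepted", path.name)
        flush()
    if not matrices:
        raise FormatError(f"{path.name}: empty matrix library")
    return matrices


def write_pwm_library(matrices: Sequence[PWMatrix], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for mat in matrices:
            fh.write(f"ID {mat.matrix_id}\n")
            for sym in mat.tf_symbols:
                fh.write(f"BF {sym}\n")
            fh.write("P0 A C G T\n")
            for i, row in enumerate(mat.counts, start=1):
                vals = " ".join(f"{v:.10g}" for v in row)
                fh.write(f"{i:02d} {vals}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# promoter FASTA
# ---------------------------------------------------------------------------


def read_promoters_fasta(
    path: str | Path,
    label_map: Mapping[str, str],
    pad_short: bool = False,
) -> PromoterSet:
    """Read promoters from FASTA, assigning yes/no labels from ``label_map``.

    Sequences are upper-cased; records shorter than 1100 bp are rejected by
    default or 5'-padded with N when ``pad_short`` is set.
    """
    path = Path(path)
    by_id: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        by_id[rec.id] = str(rec.seq).upper()
    missing = sorted(set(label_map) - set(by_id))
    if missing:
        raise FormatError(f"{path.name}: records in label_map absent from FASTA: {missing[:5]}")
    records: list[PromoterRecord] = []
    for gene_id, label in label_map.items():
        seq = by_id[gene_id]
        if len(seq) != PROMOTER_LEN:
            if pad_short and len(seq) < PROMOTER_LEN:
                seq = "N" * (PROMOTER_LEN - len(seq)) + seq
            else:
                raise FormatError(
                    f"{path.name}: {gene_id} length {len(seq)} != {PROMOTER_LEN} "
                    "(set pad_short=True to 5'-pad with N)"
                )
        if not set(seq) <= VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise FormatError(f"{path.name}: {gene_id} has invalid characters {bad}")
        records.append(PromoterRecord(gene_id=gene_id, sequence=seq, label=label))
    return PromoterSet(records=records)


def write_promoters_fasta(promoters: PromoterSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
        for r in promoters.records
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# network edge list + node annotations
# ---------------------------------------------------------------------------


def read_network(edges_path: str | Path, nodes_path: str | Path | None = None) -> NetworkEdgeList:
    """Read a directed network from an edge TSV plus optional node TSV.

    Edge file: source<TAB>target<TAB>label.  Node file columns: node,
    gene_symbols (comma-joined, may be empty), is_tf (0/1).
    """
    edges_path = Path(edges_path)
    edges: list[tuple[str, str, str]] = []
    with open(edges_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "source":
                continue
            if len(fields) < 2:
                raise FormatError(f"{edges_path.name}: line {lineno}: need source<TAB>target")
            label = fields[2] if len(fields) > 2 else ""
            edges.append((fields[0], fields[1], label))
    annotations: dict[str, NodeAnnotation] = {}
    if nodes_path is not None:
        nodes_path = Path(nodes_path)
        frame = pd.read_csv(
            nodes_path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
        for col in ("node", "gene_symbols", "is_tf"):
            if col not in frame.columns:
                raise FormatError(f"{nodes_path.name}: missing column {col!r}")
        for row in frame.itertuples(index=False):
            symbols = tuple(s for s in str(row.gene_symbols).split(",") if s)
            annotations[str(row.node)] = NodeAnnotation(
                gene_symbols=symbols,
                is_transcription_factor=str(row.is_tf) in ("1", "true", "True"),
            )
    return NetworkEdgeList(edges=edges, node_annotations=annotations)


def write_network(
    network: NetworkEdgeList,
    edges_path: str | Path,
    nodes_path: str | Path,
    config_hash: str = "none",
    seed: int | None = None,
) -> None:
    with open(edges_path, "w") as fh:
        fh.write(report_header(config_hash, seed) + "\n")
        fh.write("source\ttarget\tlabel\n")
        for src, tgt, lab in network.edges:
            fh.write(f"{src}\t{tgt}\t{lab}\n")
    with open(nodes_path, "w") as fh:
        fh.write(report_header(config_hash, seed) + "\n")
        fh.write("node\tgene_symbols\tis_tf\n")
        for node, ann in network.node_annotations.items():
            fh.write(
                f"{node}\t{','.join(ann.gene_symbols)}\t"
                f"{1 if ann.is_transcription_factor else 0}\n"
            )


# ---------------------------------------------------------------------------
# drug-target and compound-activity tables
# ---------------------------------------------------------------------------


def read_drug_table(path: str | Path) -> DrugTargetTable:
    frame = pd.read_csv(Path(path), sep="\t", comment="#", dtype=str)
    for col in ("compound_id", "target_gene", "disease_id", "max_trial_phase"):
        if col not in frame.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    frame["max_trial_phase"] = pd.to_numeric(frame["max_trial_phase"], errors="raise").astype(int)
    return DrugTargetTable(frame=frame)


def write_drug_table(
    table: DrugTargetTable, path: str | Path, config_hash: str = "none", seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(report_header(config_hash, seed) + "\n")
        fh.write("compound_id\ttarget_gene\tdisease_id\tmax_trial_phase\n")
        for row in table.frame.itertuples(index=False):
            fh.write(f"{row.compound_id}\t{row.target_gene}\t{row.disease_id}\t{row.max_trial_phase}\n")


def read_compound_table(
    activities_path: str | Path, gene_weights_path: str | Path
) -> CompoundActivityTable:
    """Read compound activities plus the per-gene IAP / optWeight table."""
    frame = pd.read_csv(Path(activities_path), sep="\t", comment="#", dtype=str,
                        keep_default_na=False)
    for col in ("compound_id", "activity_name", "activity_class", "pa", "mapped_genes"):
        if col not in frame.columns:
            raise FormatError(f"{Path(activities_path).name}: missing column {col!r}")
    frame["pa"] = pd.to_numeric(frame["pa"], errors="raise")
    weights = pd.read_csv(Path(gene_weights_path), sep="\t", comment="#", dtype=str)
    for col in ("gene", "iap", "opt_weight"):
        if col not in weights.columns:
            raise FormatError(f"{Path(gene_weights_path).name}: missing column {col!r}")
    iap = {str(r.gene): float(r.iap) for r in weights.itertuples(index=False)}
    opt = {str(r.gene): float(r.opt_weight) for r in weights.itertuples(index=False)}
    return CompoundActivityTable(frame=frame, iap=iap, opt_weight=opt)


def write_compound_table(
    table: CompoundActivityTable,
    activities_path: str | Path,
    gene_weights_path: str | Path,
    config_hash: str = "none",
    seed: int | None = None,
) -> None:
    with open(activities_path, "w") as fh:
        fh.write(report_header(config_hash, seed) + "\n")
        fh.write("compound_id\tactivity_name\tactivity_class\tpa\tmapped_genes\n")
        for row in table.frame.itertuples(index=False):
            genes = ",".join(row.mapped_genes)
            fh.write(
                f"{row.compound_id}\t{row.activity_name}\t{row.activity_class}\t"
                f"{row.pa:.10g}\t{genes}\n"
            )
    with open(gene_weights_path, "w") as fh:
        fh.write(report_header(config_hash, seed) + "\n")
        fh.write("gene\tiap\topt_weight\n")
        for gene in sorted(set(table.iap) | set(table.opt_weight)):
            fh.write(
                f"{gene}\t{table.iap.get(gene, 1.0):.10g}\t"
                f"{table.opt_weight.get(gene, 1.0):.10g}\n"
            )
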
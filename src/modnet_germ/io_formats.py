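"""Readers and writers for every tabular artifact the pipeline touches.

All tables are UTF-8 tab-separated values.  Lines starting with ``#`` are
comments and are ignored.  Gene, sample, and module identifiers are
case-sensitive opaque strings; no identifier normalization is attempted.

Parsing is strict: counts must be non-negative integers, homology hits must
have exactly twelve fields, and any sample mentioned in one table but not
the other raises :class:`ConsistencyError` rather than being silently
dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The three genotypic subsets analyzed independently.
SUBSETS = ("Mips", "MRP", "MipsMRP")

#: Canonical (alphabetical) order of the five network-inference methods,
#: used whenever method sets are serialized.
METHOD_ORDER = ("aracne", "clr", "lars", "pcor", "rf")

META_COLUMNS = (
    "sample_id",
    "line",
    "subset",
    "mips1",
    "mrp_l",
    "mrp_n",
    "phytic_class",
    "stage",
    "replicate",
)


class FormatError(ValueError):
    """A file violates its declared on-disk format."""


class ConsistencyError(ValueError):
    """Two related tables disagree (e.g. counts vs. sample metadata)."""


class DegenerateInputError(ValueError):
    """Input is syntactically valid but statistically unusable."""


def phytic_class_for(flags: tuple[bool, bool, bool]) -> str:
    """Phytic-acid class implied by (mips1, mrp_l, mrp_n) mutation flags.

    A line is low phytic acid (``lpa``) when it carries the *mips1*
    mutation or both epistatically interacting *mrp* mutations; a single
    *mrp* mutation leaves the seed phenotypically normal.
    """
    mips1, mrp_l, mrp_n = flags
    return "lpa" if (mips1 or (mrp_l and mrp_n)) else "normal"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation: line identity, genotype, subset, stage, rep."""

    sample_id: str
    line: str
    subset: str
    genotype_flags: tuple[bool, bool, bool]  # (mips1, mrp_l, mrp_n) mutated
    phytic_class: str  # "lpa" | "normal"
    stage: int  # germination stage 1 (dry), 2 (imbibed), 3 (germinated)
    replicate: int

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise FormatError(f"unknown genotypic subset {self.subset!r}")
        if self.phytic_class not in ("lpa", "normal"):
            raise FormatError(f"unknown phytic class {self.phytic_class!r}")
        if phytic_class_for(self.genotype_flags) != self.phytic_class:
            raise ConsistencyError(
                f"sample {self.sample_id}: phytic class {self.phytic_class!r} "
                f"inconsistent with genotype flags {self.genotype_flags}"
            )
        if self.stage not in (1, 2, 3):
            raise FormatError(f"stage must be 1, 2 or 3, got {self.stage}")
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    ``counts`` is a DataFrame indexed by gene id with one column per
    sample, column order matching ``samples``.
    """

    counts: pd.DataFrame
    samples: tuple[SampleMeta, ...]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate sample ids in metadata")
        if list(self.counts.columns) != ids:
            raise ConsistencyError(
                "count-matrix columns do not match metadata sample order"
            )
        cells = {(s.line, s.stage, s.replicate) for s in self.samples}
        if len(cells) != len(self.samples):
            raise ConsistencyError("(line, stage, replicate) not unique")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must have integer dtype")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, subset: str) -> list[SampleMeta]:
        return [s for s in self.samples if s.subset == subset]


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular alignment output (``outfmt 6`` layout)."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gaps: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"negative E-value for {self.query}/{self.subject}")
        if not math.isfinite(self.bitscore):
            raise FormatError(f"non-finite bitscore for {self.query}/{self.subject}")


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the per-sample metadata table (one row per sample)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            SampleMeta(
                sample_id=row.sample_id,
                line=row.line,
                subset=row.subset,
                genotype_flags=(
                    row.mips1 in ("1", "True", "true"),
                    row.mrp_l in ("1", "True", "true"),
                    row.mrp_n in ("1", "True", "true"),
                ),
                phytic_class=row.phytic_class,
                stage=int(row.stage),
                replicate=int(row.replicate),
            )
        )
    return samples


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "line": s.line,
            "subset": s.subset,
            "mips1": int(s.genotype_flags[0]),
            "mrp_l": int(s.genotype_flags[1]),
            "mrp_n": int(s.genotype_flags[2]),
            "phytic_class": s.phytic_class,
            "stage": s.stage,
            "replicate": s.replicate,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a counts TSV plus its sample metadata into a validated matrix.

    The counts file has a header row of sample ids and a first column of
    gene ids.  Sample order in the returned matrix follows the metadata
    table.  Any mismatch between the two sample-id sets, any non-integer
    literal, or any negative count raises.
    """
    samples = read_sample_meta(meta_path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)

    count_ids = set(df.columns)
    meta_ids = {s.sample_id for s in samples}
    if count_ids != meta_ids:
        only_meta = sorted(meta_ids - count_ids)
        only_counts = sorted(count_ids - meta_ids)
        raise ConsistencyError(
            f"sample-id mismatch: in metadata only {only_meta}, "
            f"in counts only {only_counts}"
        )

    for col in df.columns:
        series = df[col]
        if np.issubdtype(series.dtype, np.integer):
            continue
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric))
        gene = series.index[bad][0] if bad.any() else series.index[0]
        raise FormatError(
            f"non-integer count {series[gene]!r} at gene {gene!r}, sample {col!r}"
        )

    df = df[[s.sample_id for s in samples]]
    return CountMatrix(counts=df, samples=tuple(samples))


def write_counts(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    write_sample_meta(cm.samples, meta_path)


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column tabular alignment output, preserving row order.

    No E-value filtering is applied here; see
    :func:`modnet_germ.validation.best_hits` for the top-hit selection.
    """
    hits: list[AlignmentHit] = []
    for lineno, line in _data_lines(Path(path)):
        fields = line.split("\t")
        if len(fields) != 12:
            raise FormatError(
                f"{path}: line {lineno}: expected 12 fields, got {len(fields)}"
            )
        try:
            hits.append(
                AlignmentHit(
                    query=fields[0],
                    subject=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gaps=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_edge_list(
    edges: Iterable[tuple[str, str, int, Iterable[str]]], path: str | Path
) -> None:
    """Write consensus edges as TSV: regulator, target, support, methods.

    Methods are serialized comma-joined in the canonical order
    ``aracne,clr,lars,pcor,rf``.
    """
    lines = ["regulator\ttarget\tsupport\tmethods"]
    for regulator, target, support, methods in edges:
        methods = set(methods)
        unknown = methods - set(METHOD_ORDER)
        if unknown:
            raise ValueError(f"unknown method name(s): {sorted(unknown)}")
        if not 0 <= int(support) <= 5:
            raise ValueError(f"support must be in 0..5, got {support}")
        serialized = ",".join(m for m in METHOD_ORDER if m in methods)
        lines.append(f"{regulator}\t{target}\t{support}\t{serialized}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edge_list(path: str | Path) -> list[tuple[str, str, int, frozenset[str]]]:
    edges = []
    lines = list(_data_lines(Path(path)))
    if not lines or lines[0][1].split("\t")[:2] != ["regulator", "target"]:
        raise FormatError(f"{path}: missing edge-list header")
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}: line {lineno}: expected 4 fields")
        methods = frozenset(m for m in fields[3].split(",") if m)
        unknown = methods - set(METHOD_ORDER)
        if unknown:
            raise FormatError(f"{path}: line {lineno}: unknown methods {sorted(unknown)}")
        edges.append((fields[0], fields[1], int(fields[2]), methods))
    return edges


def read_go_map(
    path: str | Path,
) -> tuple[dict[str, set[str]], dict[str, tuple[str, str]]]:
    """Read a GO annotation table: gene, term, namespace, description.

    Returns (gene -> set of term ids, term id -> (description, namespace)).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene", "term"):
        if col not in df.columns:
            raise FormatError(f"GO map missing column {col!r}")
    go_map: dict[str, set[str]] = {}
    go_names: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        go_map.setdefault(row.gene, set()).add(row.term)
        go_names[row.term] = (
            getattr(row, "description", ""),
            getattr(row, "namespace", ""),
        )
    return go_map, go_names


def write_go_map(
    go_map: Mapping[str, set[str]],
    go_names: Mapping[str, tuple[str, str]],
    path: str | Path,
) -> None:
    rows = []
    for gene in sorted(go_map):
        for term in sorted(go_map[gene]):
            desc, ns = go_names.get(term, ("", ""))
            rows.append({"gene": gene, "term": term, "namespace": ns, "description": desc})
    pd.DataFrame(rows, columns=["gene", "term", "namespace", "description"]).to_csv(
        path, sep="\t", index=False
    )


def read_tf_map(path: str | Path) -> dict[str, str]:
    """Read a TF annotation table: gene, family."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene", "family"):
        if col not in df.columns:
            raise FormatError(f"TF map missing column {col!r}")
    return dict(zip(df["gene"], df["family"]))


def write_tf_map(tf_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene": g, "family": f} for g, f in sorted(tf_map.items())]
    ).to_csv(path, sep="\t", index=False)


def read_dap_edges(path: str | Path) -> set[tuple[str, str]]:
    """Read a regulator -> target edge table (DAP-seq interactions)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("regulator", "target"):
        if col not in df.columns:
            raise FormatError(f"DAP edge table missing column {col!r}")
    return set(zip(df["regulator"], df["target"]))


def write_dap_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(sorted(edges), columns=["regulator", "target"]).to_csv(
        path, sep="\t", index=False
    )


def read_motif_matches(path: str | Path) -> set[tuple[str, str]]:
    """Read a (module, matched TF gene) motif-match table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("module", "tf"):
        if col not in df.columns:
            raise FormatError(f"motif-match table missing column {col!r}")
    return set(zip(df["module"], df["tf"]))


def write_motif_matches(matches: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(sorted(matches), columns=["module", "tf"]).to_csv(
        path, sep="\t", index=False
    )
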
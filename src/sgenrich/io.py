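"""Readers, writers, and the core data containers.

Counts are gene-by-sample non-negative integers (TSV primary, MatrixMarket
accepted), paired with a sample sheet giving each sample's condition,
fraction (IP or input), and replicate index.  Annotation carries one
representative transcript per gene — the longest isoform whose biotype
matches the gene biotype, or the longest isoform overall for non-coding
genes — plus an optional sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRACTION_IP = "IP"
FRACTION_INPUT = "input"


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class SampleDesign:
    """Per-sample condition, fraction (IP|input), and replicate labels."""

    table: pd.DataFrame  # columns: sample_id, condition, fraction, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "fraction", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample ids in design: {list(dups)}")
        fracs = set(self.table["fraction"])
        if not fracs <= {FRACTION_IP, FRACTION_INPUT}:
            raise ValidationError(
                f"fraction must be one of {{{FRACTION_IP!r}, {FRACTION_INPUT!r}}}, got {sorted(fracs)}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in order of first appearance."""
        return list(dict.fromkeys(self.table["condition"]))

    def samples(self, condition: str | None = None, fraction: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if fraction is not None:
            mask &= self.table["fraction"] == fraction
        return list(self.table.loc[mask, "sample_id"])

    def subset(self, sample_ids: list[str]) -> "SampleDesign":
        sub = self.table[self.table["sample_id"].isin(sample_ids)].copy()
        return SampleDesign(sub)


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts plus per-sample library sizes.

    ``library_sizes`` defaults to column sums; an ``effective_size`` column
    in the design sheet may override it.
    """

    gene_ids: np.ndarray
    counts: np.ndarray  # (n_genes, n_samples) int64
    sample_ids: list[str]
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-dimensional")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError("gene_ids length does not match count rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValidationError("sample_ids length does not match count columns")
        if pd.Index(self.gene_ids).duplicated().any():
            dup = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
            raise ValidationError(f"duplicate gene id: {list(dup[:5])}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValidationError(
                    f"non-integer count at ({self.gene_ids[bad[0]]},{self.sample_ids[bad[1]]})"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at ({self.gene_ids[bad[0]]},{self.sample_ids[bad[1]]})"
            )
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
            if len(self.library_sizes) != self.counts.shape[1]:
                raise ValidationError("library_sizes length does not match samples")
        if np.any(self.library_sizes <= 0):
            bad = [s for s, l in zip(self.sample_ids, self.library_sizes) if l <= 0]
            raise ValidationError(f"non-positive library size for samples {bad}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def column_index(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in count matrix") from None

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = self.column_index(sample_ids)
        return CountMatrix(
            gene_ids=self.gene_ids.copy(),
            counts=self.counts[:, idx].copy(),
            sample_ids=list(sample_ids),
            library_sizes=self.library_sizes[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)


@dataclass
class TranscriptAnnotation:
    """One representative transcript per gene: length, biotype, optional sequence."""

    table: pd.DataFrame  # index gene_id; columns: length, biotype, [sequence]

    def __post_init__(self) -> None:
        if "length" not in self.table.columns:
            raise ValidationError("annotation requires a 'length' column")
        if (self.table["length"] < 1).any():
            bad = self.table.index[self.table["length"] < 1]
            raise ValidationError(f"length < 1 for genes {list(bad[:5])}")
        if "sequence" in self.table.columns:
            has_seq = self.table["sequence"].notna()
            seq_len = self.table.loc[has_seq, "sequence"].str.len()
            mism = seq_len != self.table.loc[has_seq, "length"]
            if mism.any():
                raise ValidationError(
                    f"sequence length mismatch for genes {list(seq_len.index[mism][:5])}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def lengths(self, gene_ids) -> np.ndarray:
        return self.table.loc[list(gene_ids), "length"].to_numpy(dtype=float)

    def sequence(self, gene_id: str) -> str:
        seq = self.table.at[gene_id, "sequence"]
        if not isinstance(seq, str):
            raise KeyError(f"no sequence for gene {gene_id!r}")
        return seq


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(path: str | Path, design_path: str | Path) -> tuple[CountMatrix, SampleDesign]:
    """Read a count matrix (TSV or MatrixMarket) together with its sample sheet.

    The TSV layout is a ``gene_id`` column followed by one column per sample.
    A MatrixMarket file ``X.mtx`` expects sibling ``X.mtx.rownames`` /
    ``X.mtx.colnames`` files (one id per line).  Every sample column must be
    described by a design row; a design column ``effective_size`` overrides
    the default column-sum library sizes.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(str(path))
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        genes = Path(str(path) + ".rownames").read_text().split()
        samples = Path(str(path) + ".colnames").read_text().split()
        frame = pd.DataFrame(mat, index=genes, columns=samples)
        frame.index.name = "gene_id"
    else:
        frame = _read_table(path)
        if frame.columns[0] != "gene_id":
            frame = frame.rename(columns={frame.columns[0]: "gene_id"})
        frame = frame.set_index("gene_id")
    if frame.isna().any().any():
        raise ValidationError("NaN entries in count matrix")

    design = SampleDesign(_read_table(design_path))
    missing = [s for s in frame.columns if s not in set(design.sample_ids)]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    missing = [s for s in design.sample_ids if s not in set(frame.columns)]
    if missing:
        raise ValidationError(f"design samples missing from counts: {missing}")
    frame = frame[design.sample_ids]

    lib = None
    if "effective_size" in design.table.columns:
        lib = design.table["effective_size"].to_numpy()
    cm = CountMatrix(
        gene_ids=frame.index.to_numpy(dtype=object),
        counts=frame.to_numpy(),
        sample_ids=list(frame.columns),
        library_sizes=lib,
    )
    return cm, design


def read_annotation(path: str | Path, fasta_path: str | Path | None = None) -> TranscriptAnnotation:
    """Read a gene/isoform table and reduce it to one representative per gene.

    The table needs columns ``gene_id``, ``length``, ``biotype`` and may carry
    one row per isoform (optional ``gene_biotype`` column giving the gene-level
    biotype).  For each gene the representative is the longest isoform whose
    biotype equals the gene biotype; if no isoform matches (e.g. non-coding
    genes annotated only through processed isoforms) the longest isoform
    overall is taken.  Sequences from ``fasta_path`` are attached by gene id.
    """
    tab = _read_table(path)
    required = {"gene_id", "length", "biotype"}
    missing = required - set(tab.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")

    rows = []
    for gene_id, grp in tab.groupby("gene_id", sort=False):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            logger.warning("gene %s has zero isoforms; excluded", gene_id)
            continue
        if "gene_biotype" in grp.columns:
            gene_bt = grp["gene_biotype"].iloc[0]
        else:
            gene_bt = grp["biotype"].iloc[0]
        same = grp[grp["biotype"] == gene_bt]
        pick_from = same if len(same) else grp
        best = pick_from.loc[pick_from["length"].idxmax()]
        rows.append({"gene_id": gene_id, "length": int(best["length"]), "biotype": best["biotype"]})
    out = pd.DataFrame(rows).set_index("gene_id")

    if fasta_path is not None:
        seqs = read_fasta(fasta_path)
        unmatched = [g for g in seqs if g not in out.index]
        if unmatched:
            raise ValidationError(f"FASTA ids not in annotation: {unmatched[:5]}")
        out["sequence"] = pd.Series(seqs)
    return TranscriptAnnotation(out)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {id: sequence}."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_flags(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, flag) -> boolean Series indexed by gene."""
    tab = _read_table(path)
    gene_col, flag_col = tab.columns[0], tab.columns[1]
    return tab.set_index(gene_col)[flag_col].astype(bool)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  params: dict | None = None) -> dict:
    """Write one TSV per table plus a JSON run summary; returns the manifest.

    Column order is preserved as given so reruns with identical inputs are
    byte-identical.  The manifest records parameters (including any seeds)
    and the written file list.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, tab in tables.items():
        dest = out_dir / f"{name}.tsv"
        tab.to_csv(dest, sep="\t", index=tab.index.name is not None)
        files.append(dest.name)
    manifest = {
        "parameters": params or {},
        "tables": files,
        "package": "sgenrich",
    }
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
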
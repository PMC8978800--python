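"""Reading and writing the pipeline's file formats, plus run configuration.

Formats: FASTA for protein sequences (via Biopython), two-column TSV for
interaction edge lists, CSV for labeled pairs and predictions, YAML/JSON
for configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ConfigError, EdgeListFormatError, FastaFormatError, PredictionWriteError

logger = logging.getLogger(__name__)

#: the 20 canonical amino acids
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: tolerated ambiguity / non-standard codes (kept as literal residues)
AMBIGUOUS_AA = set("BJOUXZ")
VALID_AA = CANONICAL_AA | AMBIGUOUS_AA


@dataclass(frozen=True)
class SequenceRecord:
    """A protein identifier with its (uppercase) amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("empty sequence identifier")
        if not self.sequence:
            raise FastaFormatError(f"empty sequence for record {self.id!r}")


@dataclass(frozen=True)
class EdgeRecord:
    """An undirected interaction between two proteins."""

    protein_a: str
    protein_b: str

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise EdgeListFormatError("empty protein identifier in edge")

    def key(self) -> tuple[str, str]:
        """Canonical unordered representation."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords.

    Sequences are uppercased and multi-line entries concatenated; record
    order is preserved. Raises :class:`FastaFormatError` on empty sequences,
    empty headers, or duplicate IDs.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rec_id = title.split()[0] if title.split() else ""
            if not rec_id:
                raise FastaFormatError(f"{path}: FASTA header with no identifier")
            if rec_id in seen:
                raise FastaFormatError(f"{path}: duplicate FASTA identifier {rec_id!r}")
            seq = seq.upper().replace(" ", "")
            if not seq:
                raise FastaFormatError(f"{path}: empty sequence for {rec_id!r}")
            bad = set(seq) - VALID_AA
            if bad:
                raise FastaFormatError(
                    f"{path}: record {rec_id!r} contains non-amino-acid characters {sorted(bad)}"
                )
            seen.add(rec_id)
            records.append(SequenceRecord(rec_id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    """Parse a whitespace/tab separated two-column edge list.

    Duplicate edges and both orientations collapse to a single undirected
    edge (first-seen order preserved); self-loops are dropped and counted in
    a log message. A line with a field count other than two raises
    :class:`EdgeListFormatError` naming the line number. A single header
    line is tolerated if its first field is one of the conventional names.
    """
    edges: list[EdgeRecord] = []
    seen: set[tuple[str, str]] = set()
    n_self = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if lineno == 1 and fields[0].lower() in {"protein_a", "source", "node1", "id_a"}:
                continue
            if len(fields) != 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected 2 fields, found {len(fields)}"
                )
            a, b = fields
            if a == b:
                n_self += 1
                continue
            rec = EdgeRecord(a, b)
            if rec.key() in seen:
                continue
            seen.add(rec.key())
            edges.append(rec)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    return edges


def write_edge_list(edges: Iterable[EdgeRecord], path: str | Path) -> None:
    """Write edges as a canonical two-column TSV (unordered keys, input order)."""
    with open(path, "w") as handle:
        for e in edges:
            a, b = e.key()
            handle.write(f"{a}\t{b}\n")


def read_labeled_pairs(path: str | Path) -> tuple[list[tuple[str, str]], list[int]]:
    """Read a CSV with columns protein_a, protein_b, label (0/1)."""
    df = pd.read_csv(path, dtype={"protein_a": str, "protein_b": str})
    labels = df["label"].astype(int).tolist()
    pairs = list(zip(df["protein_a"], df["protein_b"]))
    return pairs, labels


def write_labeled_pairs(
    pairs: Sequence[tuple[str, str]], labels: Sequence[int], path: str | Path
) -> None:
    pd.DataFrame(
        {"protein_a": [p[0] for p in pairs], "protein_b": [p[1] for p in pairs], "label": labels}
    ).to_csv(path, index=False)


def write_predictions(
    pairs: Sequence[tuple[str, str]], scores: Sequence[float], path: str | Path
) -> None:
    """Write pair scores as CSV (protein_a, protein_b, score), input order.

    Raises :class:`PredictionWriteError` on length mismatch or scores
    outside [0, 1]. Full float precision is preserved (repr round-trip).
    """
    if len(pairs) != len(scores):
        raise PredictionWriteError(
            f"{len(pairs)} pairs but {len(scores)} scores"
        )
    if any(s < 0 or s > 1 for s in scores):
        raise PredictionWriteError("scores must lie in [0, 1]")
    with open(path, "w") as handle:
        handle.write("protein_a,protein_b,score\n")
        for (a, b), s in zip(pairs, scores):
            handle.write(f"{a},{b},{s!r}\n")


def read_predictions(path: str | Path) -> tuple[list[tuple[str, str]], list[float]]:
    df = pd.read_csv(path, dtype={"protein_a": str, "protein_b": str})
    return list(zip(df["protein_a"], df["protein_b"])), df["score"].astype(float).tolist()


@dataclass
class RunConfig:
    """All pipeline hyperparameters in one flat record.

    Defaults follow the published method where it states a choice
    (k = 4, sigma = 64, five folds) and documented conventions elsewhere.
    """

    # sequence (attribute) channel
    k: int = 4
    sigma: int = 64
    cbow_window: int = 5
    cbow_epochs: int = 5
    cbow_learning_rate: float = 0.05
    pooling: str = "mean"  # mean | sum | max
    # graph (behavior) channel
    walk_length: int = 32
    walks_per_node: int = 10
    window: int = 5
    sg_epochs: int = 5
    sg_learning_rate: float = 0.025
    transductive: bool = False
    # classifier
    tower_widths: tuple[int, ...] = (128,)
    fused_widths: tuple[int, ...] = (256, 128, 64)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 120
    batch_size: int = 256
    patience: int = 0  # 0 disables early stopping
    val_fraction: float = 0.1
    share_towers: bool = False
    symmetrize: bool = True
    precision: str = "float32"  # float32 | float64
    # evaluation
    folds: int = 5
    stratified: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.sigma < 1:
            raise ConfigError("sigma must be >= 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.walk_length < 1 or self.walks_per_node < 1 or self.window < 1:
            raise ConfigError("walk/window parameters must be >= 1")
        if not self.tower_widths or not self.fused_widths:
            raise ConfigError("tower and fused stages each need >= 1 layer")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        if self.pooling not in {"mean", "sum", "max"}:
            raise ConfigError(f"unknown pooling {self.pooling!r}")
        if self.precision not in {"float32", "float64"}:
            raise ConfigError(f"unknown precision {self.precision!r}")
        self.tower_widths = tuple(self.tower_widths)
        self.fused_widths = tuple(self.fused_widths)

    @property
    def t1(self) -> int:
        """Depth of each per-protein tower."""
        return len(self.tower_widths)

    @property
    def t2(self) -> int:
        """Total depth: towers + fused hidden layers + output layer."""
        return self.t1 + len(self.fused_widths) + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tower_widths"] = list(self.tower_widths)
        d["fused_widths"] = list(self.fused_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load from YAML (or JSON, a YAML subset)."""
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
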
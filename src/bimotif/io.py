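"""Sequence input, JSON model persistence and sliding-window scoring."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import BmfModel, EnergyTable, SpacerParams
from .sequences import normalize_sequence
from .thermo import binding_probability

__all__ = [
    "read_sequences",
    "write_model",
    "read_model",
    "ScoreRecord",
    "sliding_windows",
    "predict_scores",
    "write_scores",
    "write_fasta",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def read_sequences(path, fmt: str = "fasta") -> list[tuple[str, str]]:
    """(id, sequence) pairs from FASTA or one-sequence-per-line text.

    Sequences are normalized (uppercase, T->U).  Plain format uses 1-based
    line numbers as ids.  Empty records are skipped with a warning.
    """
    records: list[tuple[str, str]] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = normalize_sequence(str(rec.seq))
            if not seq:
                logger.warning("skipping empty FASTA record %r", rec.id)
                continue
            records.append((rec.id, seq))
    elif fmt == "plain":
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                seq = normalize_sequence(line.strip())
                if not seq:
                    logger.warning("skipping empty line %d", lineno)
                    continue
                records.append((str(lineno), seq))
    else:
        raise ValueError(f"unknown sequence format {fmt!r} (expected fasta or plain)")
    if not records:
        logger.warning("no sequences read from %s", path)
    return records


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")


def write_model(model: BmfModel, path, metadata: dict | None = None) -> None:
    """Persist a model as JSON.

    Floats are written with full (shortest round-trip) precision, so a
    write/read cycle reproduces every parameter bit-exactly.
    """
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": model.k,
        "energies_a": model.core_a.energies.tolist(),
        "energies_b": model.core_b.energies.tolist(),
        "rho": model.spacer.rho,
        "pi": model.spacer.pi,
        "scale_param": model.spacer.scale_param,
        "metadata": metadata or {},
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1)
        handle.write("\n")


def read_model(path) -> tuple[BmfModel, dict]:
    """Load a model written by :func:`write_model`; returns (model, metadata)."""
    with open(path) as handle:
        try:
            doc = json.load(handle)
        except json.JSONDecodeError as err:
            raise ValueError(f"unparseable model file {path}: {err}") from err
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file {path} has format version {version!r}; this build "
            f"reads version {MODEL_FORMAT_VERSION}"
        )
    k = int(doc["k"])
    model = BmfModel(
        core_a=EnergyTable(k, np.array(doc["energies_a"], dtype=np.float64)),
        core_b=EnergyTable(k, np.array(doc["energies_b"], dtype=np.float64)),
        spacer=SpacerParams(
            rho=float(doc["rho"]),
            pi=float(doc["pi"]),
            scale_param=float(doc["scale_param"]),
        ),
    )
    return model, doc.get("metadata", {})


@dataclass
class ScoreRecord:
    """Per-sequence prediction: mean binding probability over windows."""

    sequence_id: str
    score: float
    n_windows: int


def sliding_windows(L: int, window: int = 50, stride: int = 20) -> list[tuple[int, int]]:
    """Half-open [start, end) windows covering a sequence of length L.

    One whole-sequence window when L <= window; otherwise stride-spaced
    starts from 0 plus a final right-anchored window ending at L so coverage
    is complete; a duplicate anchor window is emitted once.  Requires
    1 <= stride <= window (a larger stride could not cover the sequence).
    """
    if not 1 <= stride <= window:
        raise ValueError("stride must be in [1, window] for full coverage")
    if L <= window:
        return [(0, L)]
    starts = list(range(0, L - window + 1, stride))
    if starts[-1] != L - window:
        starts.append(L - window)
    return [(s, s + window) for s in starts]


def predict_scores(
    model: BmfModel,
    sequences: list[tuple[str, str]],
    window: int = 50,
    stride: int = 20,
) -> list[ScoreRecord]:
    """Score each (id, sequence): arithmetic mean of per-window binding
    probabilities.  Empty sequences score 0 (Z = 1) and are logged."""
    if not sequences:
        raise ValueError("no sequences to score")
    out = []
    for name, seq in sequences:
        if len(seq) == 0:
            logger.warning("sequence %r is empty; score 0", name)
            out.append(ScoreRecord(name, 0.0, 1))
            continue
        spans = sliding_windows(len(seq), window, stride)
        probs = [binding_probability(seq[a:b], model) for a, b in spans]
        out.append(ScoreRecord(name, float(np.mean(probs)), len(spans)))
    return out


def write_scores(records: list[ScoreRecord], path) -> None:
    """TSV with columns id, score, n_windows."""
    frame = pd.DataFrame(
        {
            "id": [r.sequence_id for r in records],
            "score": [r.score for r in records],
            "n_windows": [r.n_windows for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
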
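"""Reading and writing syllable tables and corpus files.

Per-syllable data travels as CSV (one row per syllable, times in seconds,
optional ``feature_0..feature_{d-1}`` columns); corpus structure —
which rows form which sequence, plus the label alphabet — travels as a
small JSON sidecar referencing row indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus, LabelAlphabet, Syllable, SyllableSequence, segment_into_sequences

SCHEMA_VERSION = 1


def syllables_to_frame(syllables: list[Syllable]) -> pd.DataFrame:
    rows = []
    for s in syllables:
        row = {
            "start_s": s.start_time,
            "end_s": s.end_time,
            "mean_freq_hz": s.mean_frequency,
            "jump_count": s.jump_count,
            "jump_dirs": ";".join(s.jump_directions) if s.jump_directions else "",
            "label": s.label,
        }
        if s.features is not None:
            row.update({f"feature_{i}": v for i, v in enumerate(s.features)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_syllables(df: pd.DataFrame) -> list[Syllable]:
    feature_cols = sorted(
        (c for c in df.columns if c.startswith("feature_")),
        key=lambda c: int(c.split("_")[1]),
    )
    syllables = []
    for _, row in df.iterrows():
        dirs = None
        if isinstance(row.get("jump_dirs"), str) and row["jump_dirs"]:
            dirs = tuple(row["jump_dirs"].split(";"))
        jump_count = row.get("jump_count")
        label = row.get("label")
        mean_f = row.get("mean_freq_hz")
        syllables.append(
            Syllable(
                start_time=float(row["start_s"]),
                end_time=float(row["end_s"]),
                mean_frequency=None if pd.isna(mean_f) else float(mean_f),
                jump_count=None if pd.isna(jump_count) else int(jump_count),
                jump_directions=dirs,
                features=np.array([row[c] for c in feature_cols], dtype=float)
                if feature_cols
                else None,
                label=None if pd.isna(label) else str(label),
            )
        )
    return syllables


def save_syllable_table(syllables: list[Syllable], path: str | Path) -> None:
    syllables_to_frame(syllables).to_csv(path, index=False)


def load_syllable_table(path: str | Path) -> list[Syllable]:
    return frame_to_syllables(pd.read_csv(path))


def save_corpus(corpus: Corpus, csv_path: str | Path, json_path: str | Path) -> None:
    """Write a corpus as a syllable CSV plus a JSON structure sidecar."""
    flat = [s for seq in corpus.sequences for s in seq]
    save_syllable_table(flat, csv_path)
    idx = 0
    seq_rows = []
    for seq in corpus.sequences:
        seq_rows.append(list(range(idx, idx + len(seq))))
        idx += len(seq)
    obj = {
        "schema": SCHEMA_VERSION,
        "alphabet": list(corpus.alphabet.symbols) if corpus.alphabet else None,
        "provenance": corpus.provenance,
        "sequences": seq_rows,
    }
    Path(json_path).write_text(json.dumps(obj))


def load_corpus(csv_path: str | Path, json_path: str | Path | None = None,
                isi_threshold: float = 0.160) -> Corpus:
    """Load a corpus; without a JSON sidecar, sequences are re-derived by
    ISI segmentation at ``isi_threshold``."""
    syllables = load_syllable_table(csv_path)
    if json_path is None:
        return Corpus(sequences=segment_into_sequences(syllables, isi_threshold))
    obj = json.loads(Path(json_path).read_text())
    sequences = [SyllableSequence([syllables[i] for i in idxs]) for idxs in obj["sequences"]]
    alphabet = LabelAlphabet(tuple(obj["alphabet"])) if obj.get("alphabet") else None
    return Corpus(sequences=sequences, alphabet=alphabet, provenance=obj.get("provenance", ""))
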
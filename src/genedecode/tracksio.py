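"""On-disk container for per-base tracks: a flat numpy ``.npz`` archive.

Keys are ``"{contig}|{strand}|{array}"``; arrays are ``class`` / ``phase``
(+ ``mask`` for label tracks).  Strand tracks are stored in strand-local
orientation, matching the in-memory convention.
"""

from __future__ import annotations

import numpy as np

from .encoding import LabeledTracks
from .predict import PredictionTracks


def _split(key: str):
    contig, strand, name = key.rsplit("|", 2)
    return contig, strand, name


def save_prediction_tracks(path, preds: dict) -> None:
    arrays = {}
    for (contig, strand), tr in preds.items():
        arrays[f"{contig}|{strand}|class"] = tr.class_probs.astype(np.float32)
        arrays[f"{contig}|{strand}|phase"] = tr.phase_probs.astype(np.float32)
    np.savez_compressed(path, **arrays)


def load_prediction_tracks(path) -> dict:
    with np.load(path) as z:
        data = {k: z[k] for k in z.files}
    out = {}
    for key, arr in data.items():
        contig, strand, name = _split(key)
        if name != "class":
            continue
        out[(contig, strand)] = PredictionTracks(
            class_probs=arr.astype(np.float64),
            phase_probs=data[f"{contig}|{strand}|phase"].astype(np.float64),
            contig_id=contig,
            strand=strand,
        )
    return out


def save_label_tracks(path, labels: dict) -> None:
    arrays = {}
    for (contig, strand), tr in labels.items():
        arrays[f"{contig}|{strand}|class"] = tr.genic_class.astype(np.float32)
        arrays[f"{contig}|{strand}|phase"] = tr.phase.astype(np.float32)
        arrays[f"{contig}|{strand}|mask"] = tr.mask
    np.savez_compressed(path, **arrays)


def load_label_tracks(path) -> dict:
    with np.load(path) as z:
        data = {k: z[k] for k in z.files}
    out = {}
    for key, arr in data.items():
        contig, strand, name = _split(key)
        if name != "class":
            continue
        out[(contig, strand)] = LabeledTracks(
            genic_class=arr,
            phase=data[f"{contig}|{strand}|phase"],
            mask=data[f"{contig}|{strand}|mask"],
            contig_id=contig,
            strand=strand,
        )
    return out
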
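"""Benchmark helpers: compare pipeline output against planted ground truth."""

from __future__ import annotations

import numpy as np

from .imaging import NucleusSegment, Track
from .synthetic import GroundTruth


def match_segments_to_truth(
    segments: list[NucleusSegment], truth: GroundTruth
) -> dict[int, int]:
    """Map each segment label to the planted nucleus label whose centre is
    nearest to the segment centroid."""
    mapping: dict[int, int] = {}
    for seg in segments:
        c = np.array(seg.centroid)
        nearest = min(
            truth.nuclei, key=lambda n: float(np.linalg.norm(c - np.array(n.center)))
        )
        mapping[seg.label] = nearest.label
    return mapping


def tracking_link_accuracy(
    tracks: list[Track],
    frame_segments: list[list[NucleusSegment]],
    truths: list[GroundTruth],
    parent_maps: list[dict[int, int]],
) -> float:
    """Fraction of frame-to-frame links that agree with the planted identity.

    A link (frame f−1, label p) → (frame f, label c) is correct when the
    planted nucleus matched to c maps (through the recorded parent map) to
    the planted nucleus matched to p.
    """
    seg_to_truth = [
        match_segments_to_truth(segs, truth)
        for segs, truth in zip(frame_segments, truths)
    ]
    correct = total = 0
    for track in tracks:
        for (f0, l0), (f1, l1) in zip(track.items, track.items[1:]):
            total += 1
            planted_prev = seg_to_truth[f0][l0]
            planted_curr = seg_to_truth[f1][l1]
            expected_prev = parent_maps[f1].get(planted_curr, planted_curr)
            correct += expected_prev == planted_prev
    return correct / total if total else float("nan")
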
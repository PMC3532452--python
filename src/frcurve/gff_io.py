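"""File formats: GFF3 feature/truth annotations, curve tables, FASTA.

GFF3 output is 1-based inclusive (internal coordinates are 0-based
half-open); ``##sequence-region`` pragmas carry the contig lengths so the
files round-trip without the assembly at hand.  Curve files are plain
whitespace-separated ``tau coverage_percent`` tables.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

from .curves import FRCurvePoint
from .feature_detection import FeatureRegion, FeatureType
from .validation import TruthSet

__all__ = [
    "write_fasta",
    "read_fasta_lengths",
    "write_feature_gff",
    "read_feature_gff",
    "write_truth_gff",
    "read_truth_gff",
    "write_curves",
    "read_curve",
    "plot_curves",
]

log = logging.getLogger("frcurve")

GFF_SOURCE = "frcurve"


def write_fasta(records: Sequence[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta_lengths(path: str) -> dict[str, int]:
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def _write_gff(path: str, rows, lengths: Optional[Mapping[str, int]],
               source: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if lengths:
            for cid in sorted(lengths):
                fh.write(f"##sequence-region {cid} 1 {lengths[cid]}\n")
        for cid, start, end, ftype, score, attrs in rows:
            score_s = "." if score is None else f"{score:.4f}"
            fh.write("\t".join([
                cid, source, ftype, str(start + 1), str(end),
                score_s, ".", ".", attrs,
            ]) + "\n")


def write_feature_gff(
    features: Sequence[FeatureRegion],
    path: str,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write features as GFF3 (type column = feature name, 1-based inclusive)."""
    ordered = list(features)
    if ordered != sorted(ordered, key=lambda r: (r.contig_id, r.start)):
        log.warning("features were not sorted by (contig, start); sorting")
        ordered.sort(key=lambda r: (r.contig_id, r.start, r.end, r.type.value))
    rows = [
        (r.contig_id, r.start, r.end, r.type.value, r.score,
         f"library={r.type.library_role.value}")
        for r in ordered
    ]
    _write_gff(path, rows, contig_lengths, GFF_SOURCE)


def read_feature_gff(path: str) -> tuple[list[FeatureRegion], dict[str, int]]:
    """Read a feature GFF3 back; returns (features, contig lengths from
    ##sequence-region pragmas, possibly empty)."""
    features: list[FeatureRegion] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, cid, _, end = line.split()
                lengths[cid] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            cid, _, ftype, start, end, score = cols[0], cols[1], cols[2], cols[3], cols[4], cols[5]
            features.append(FeatureRegion(
                cid, int(start) - 1, int(end), FeatureType(ftype),
                0.0 if score == "." else float(score)))
    return features, lengths


def write_truth_gff(truth: TruthSet, path: str) -> None:
    rows = [
        (cid, start, end, etype, None, f"event={etype}")
        for cid, start, end, etype in truth.intervals
    ]
    _write_gff(path, rows, truth.assembly_lengths, "truth")


def read_truth_gff(path: str,
                   assembly_lengths: Optional[Mapping[str, int]] = None) -> TruthSet:
    intervals: list[tuple[str, int, int, str]] = []
    lengths: dict[str, int] = dict(assembly_lengths or {})
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, cid, _, end = line.split()
                lengths.setdefault(cid, int(end))
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            intervals.append((cols[0], int(cols[3]) - 1, int(cols[4]), cols[2]))
    return TruthSet(intervals=intervals, assembly_lengths=lengths)


def write_curves(
    global_curve: Sequence[FRCurvePoint],
    per_feature_curves: Mapping[FeatureType, Sequence[FRCurvePoint]],
    prefix: str,
) -> list[str]:
    """``<prefix>_FRC.txt`` plus one ``<prefix>_<TYPE>_FRC.txt`` per feature
    type; two columns, coverage printed as percent with 2 decimals."""
    paths = []

    def write_one(path: str, curve: Sequence[FRCurvePoint]) -> None:
        with open(path, "w") as fh:
            fh.write("# tau coverage_pct\n")
            for pt in curve:
                fh.write(f"{pt.tau} {100.0 * pt.coverage:.2f}\n")
        paths.append(path)

    write_one(f"{prefix}_FRC.txt", global_curve)
    for ftype in FeatureType:
        if ftype in per_feature_curves:
            write_one(f"{prefix}_{ftype.value}_FRC.txt", per_feature_curves[ftype])
    return paths


def read_curve(path: str) -> list[FRCurvePoint]:
    points = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            tau, pct = line.split()
            points.append(FRCurvePoint(int(tau), float(pct) / 100.0))
    return points


def plot_curves(global_curve: Sequence[FRCurvePoint], path: str,
                label: str = "assembly") -> None:
    """Optional PNG plot of the global curve (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step([p.tau for p in global_curve],
            [100.0 * p.coverage for p in global_curve],
            where="post", label=label)
    ax.set_xlabel("feature threshold tau")
    ax.set_ylabel("approx. genome coverage (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
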
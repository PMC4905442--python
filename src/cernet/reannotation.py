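"""Microarray probe re-annotation from probe->transcript alignment hits.

Probes of an expression array are re-assigned to coding and long
non-coding transcripts from their BLAST alignments, through a
three-level quality filter:

1. drop probes that hit both a coding and a non-coding transcript, and
   split the remainder into a coding and a non-coding set;
2. within each set, drop probes that hit more than one transcript;
3. within each set, keep only transcripts that retain more than three
   (i.e. at least four) perfectly matching probes.

"Perfect" defaults to 100% identity over the full probe length; both
thresholds are configurable. The filters are applied sequentially in
this order — a transcript that loses probes at step 2 can then fail
step 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from cernet.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

TRANSCRIPT_CLASSES = ("coding", "noncoding")


@dataclass(frozen=True)
class ProbeHit:
    """One probe->transcript alignment hit."""

    probe_id: str
    transcript_id: str
    transcript_class: str  # "coding" | "noncoding"
    identity_pct: float
    aligned_len: int
    probe_len: int

    def __post_init__(self) -> None:
        if self.transcript_class not in TRANSCRIPT_CLASSES:
            raise ValueError(f"unknown transcript class {self.transcript_class!r}")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct out of [0,100]: {self.identity_pct}")
        if self.aligned_len > self.probe_len:
            raise ValueError("aligned_len exceeds probe_len")


@dataclass
class AnnotationSet:
    """Probe->transcript assignments for one transcript class.

    Each probe maps to exactly one transcript and each retained
    transcript carries at least ``min_probes`` probes (4 by default in
    the filter that produces these sets).
    """

    probe_to_transcript: dict[str, str] = field(default_factory=dict)
    transcript_class: str = "coding"

    def transcripts(self) -> set[str]:
        return set(self.probe_to_transcript.values())

    def probes_of(self, transcript_id: str) -> set[str]:
        return {p for p, t in self.probe_to_transcript.items() if t == transcript_id}

    def __len__(self) -> int:
        return len(self.probe_to_transcript)


def is_perfect(hit: ProbeHit, min_identity: float = 100.0,
               require_full_length: bool = True) -> bool:
    """Whether a hit counts as a perfect probe->transcript match."""
    if hit.identity_pct < min_identity:
        return False
    if require_full_length and hit.aligned_len != hit.probe_len:
        return False
    return True


def filter_hits(hits: Iterable[ProbeHit], min_identity: float = 100.0,
                require_full_length: bool = True,
                min_probes: int = 4
                ) -> tuple[AnnotationSet, AnnotationSet, dict]:
    """Apply the three-level quality filter to alignment hits.

    Returns (coding set, noncoding set, report). The report counts
    probes and transcripts surviving each step, mirroring the
    bookkeeping style of array re-annotation studies.
    """
    perfect = [h for h in hits if is_perfect(h, min_identity, require_full_length)]
    # collapse duplicate (probe, transcript) hits
    pairs: dict[tuple[str, str], str] = {}
    for h in perfect:
        key = (h.probe_id, h.transcript_id)
        prev = pairs.setdefault(key, h.transcript_class)
        if prev != h.transcript_class:
            raise ValueError(
                f"transcript {h.transcript_id!r} annotated with two classes"
            )

    by_probe: dict[str, dict[str, set[str]]] = {}
    for (probe, transcript), cls in pairs.items():
        by_probe.setdefault(probe, {"coding": set(), "noncoding": set()})
        by_probe[probe][cls].add(transcript)

    report: dict = {
        "n_hits": sum(1 for _ in perfect),
        "n_perfect_pairs": len(pairs),
        "n_probes_perfect": len(by_probe),
    }

    out: dict[str, AnnotationSet] = {}
    for cls in TRANSCRIPT_CLASSES:
        # step 1: cross-class probes removed, remainder split by class
        cls_probes = {
            p: tx[cls] for p, tx in by_probe.items()
            if tx[cls] and not tx["coding" if cls == "noncoding" else "noncoding"]
        }
        n_after_cross = len(cls_probes)
        # step 2: probes hitting >1 transcript of this class removed
        unique_probes = {p: next(iter(ts)) for p, ts in cls_probes.items()
                         if len(ts) == 1}
        n_after_unique = len(unique_probes)
        # step 3: transcripts with fewer than min_probes surviving probes removed
        counts: dict[str, int] = {}
        for t in unique_probes.values():
            counts[t] = counts.get(t, 0) + 1
        kept_tx = {t for t, c in counts.items() if c >= min_probes}
        final = {p: t for p, t in unique_probes.items() if t in kept_tx}
        out[cls] = AnnotationSet(final, transcript_class=cls)
        report[cls] = {
            "probes_after_cross_class": n_after_cross,
            "probes_after_unique": n_after_unique,
            "transcripts_kept": len(kept_tx),
            "probes_kept": len(final),
        }
    logger.info("filter_hits report: %s", report)
    return out["coding"], out["noncoding"], report


def read_blast_hits(path: str | Path, class_of: Mapping[str, str],
                    probe_len: int = 25) -> list[ProbeHit]:
    """Read BLAST outfmt-6 style 12-column TSV into :class:`ProbeHit` rows.

    Columns used: qseqid (probe), sseqid (transcript), pident, length.
    outfmt 6 does not carry the query length, so ``probe_len`` is a
    parameter (default 25 nt, the standard expression-array probe
    length). ``class_of`` maps transcript ids to "coding"/"noncoding";
    hits on unclassified transcripts raise.
    """
    hits: list[ProbeHit] = []
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 columns")
            probe, transcript = fields[0], fields[1]
            if transcript not in class_of:
                raise ValueError(
                    f"{path}:{lineno}: transcript {transcript!r} has no class entry"
                )
            hits.append(ProbeHit(
                probe_id=probe,
                transcript_id=transcript,
                transcript_class=class_of[transcript],
                identity_pct=float(fields[2]),
                aligned_len=min(int(fields[3]), probe_len),
                probe_len=probe_len,
            ))
    return hits


def read_transcript_classes(path: str | Path) -> dict[str, str]:
    """Two-column TSV: transcript_id, class ("coding"/"noncoding")."""
    out: dict[str, str] = {}
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need 2 columns")
            if fields[1] not in TRANSCRIPT_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown class {fields[1]!r}")
            out[fields[0]] = fields[1]
    return out


def summarize_to_transcripts(expr: ExpressionMatrix, ann: AnnotationSet,
                             method: str = "mean") -> ExpressionMatrix:
    """Aggregate probe-level expression to transcript level.

    Per transcript and sample, its probes are combined by ``method``
    ("mean" or "median").
    """
    if method not in ("mean", "median"):
        raise ValueError(f"method must be mean or median, got {method!r}")
    missing = sorted(set(ann.probe_to_transcript) - set(expr.values.index))
    if missing:
        raise ValueError(f"probes in annotation missing from expression: {missing}")
    probes = list(ann.probe_to_transcript)
    sub = expr.values.loc[probes]
    groups = pd.Series({p: ann.probe_to_transcript[p] for p in probes})
    agg = sub.groupby(groups).mean() if method == "mean" else sub.groupby(groups).median()
    agg = agg.sort_index()
    return ExpressionMatrix(agg, dict(expr.group_of))
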
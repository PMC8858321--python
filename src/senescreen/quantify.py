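"""Read-to-guide assignment and library-representation QC.

Amplicon reads carry the 20-nt spacer at a fixed offset behind a constant
vector sequence, so exact matching of the 20-mer at that offset against the
library is the reproducible baseline assignment rule; an optional
1-mismatch mode tolerates sequencing errors when the rescue is unambiguous.
Coverage QC reports the fraction of library guides detected above a read
floor, the standard check that library representation survived infection
and selection bottlenecks.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .library import SPACER_LEN, SgRNALibrary


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be parsed (includes record index)."""


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt", encoding="utf-8")


def _iter_reads(path):
    """Yield read sequences (str); wrap parser errors with a record index."""
    with _open_maybe_gzip(path) as fh:
        it = SeqIO.parse(fh, "fastq")
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as err:
                raise FastqParseError(
                    f"{path}: malformed FASTQ around record {i}: {err}"
                ) from None
            yield str(rec.seq)
            i += 1


def detect_offset(path, lib: SgRNALibrary, n_probe: int = 200) -> int:
    """Guess the spacer offset by exact-matching the first reads at every shift."""
    spacers = {r.spacer for r in lib}
    reads = []
    for seq in _iter_reads(path):
        reads.append(seq)
        if len(reads) >= n_probe:
            break
    if not reads:
        return 0
    best_offset, best_hits = 0, -1
    max_off = max(len(s) for s in reads) - SPACER_LEN
    for off in range(max(0, max_off) + 1):
        hits = sum(1 for s in reads if s[off : off + SPACER_LEN] in spacers)
        if hits > best_hits:
            best_offset, best_hits = off, hits
    return best_offset


def _mismatch_lookup(kmer: str, exact: dict[str, str]) -> str | None:
    """Unique guide id reachable by one substitution from ``kmer``, else None."""
    hits: set[str] = set()
    for i, orig in enumerate(kmer):
        for b in "ACGT":
            if b == orig:
                continue
            hit = exact.get(kmer[:i] + b + kmer[i + 1 :])
            if hit is not None:
                hits.add(hit)
                if len(hits) > 1:
                    return None
    return hits.pop() if len(hits) == 1 else None


def count_reads(
    fastq_path,
    lib: SgRNALibrary,
    offset: int | str = "auto",
    allow_mismatch: int = 0,
) -> tuple[pd.Series, int]:
    """Assign FASTQ reads to library guides.

    A read is assigned to guide g iff its 20-mer at ``offset`` equals g's
    spacer exactly, or — with ``allow_mismatch=1`` — differs by one
    substitution that reaches exactly one library spacer. Ambiguous rescues
    and reads too short to contain the 20-mer are tallied as unassigned,
    never double-counted.

    Returns (per-guide counts aligned to the library order, n_unassigned).
    """
    if allow_mismatch not in (0, 1):
        raise ValueError("allow_mismatch must be 0 or 1")
    if offset == "auto":
        offset = detect_offset(fastq_path, lib)
    offset = int(offset)
    if offset < 0:
        raise ValueError("offset must be non-negative")

    exact = {r.spacer: r.sgrna_id for r in lib}
    counts: dict[str, int] = {r.sgrna_id: 0 for r in lib}
    unassigned = 0
    for seq in _iter_reads(fastq_path):
        kmer = seq[offset : offset + SPACER_LEN]
        if len(kmer) < SPACER_LEN:
            unassigned += 1
            continue
        sg = exact.get(kmer)
        if sg is None and allow_mismatch:
            sg = _mismatch_lookup(kmer, exact)
        if sg is None:
            unassigned += 1
        else:
            counts[sg] += 1
    series = pd.Series(counts, name="count").reindex(lib.sgrna_ids)
    series.index.name = "sgrna_id"
    return series, unassigned


@dataclass
class CoverageReport:
    """Library-representation QC for one sample."""

    n_sgrna: int
    n_detected: int
    coverage: float
    n_reads_total: int
    n_reads_unassigned: int
    counts: pd.Series

    def to_json(self, path=None) -> str:
        payload = {
            "n_sgrna": self.n_sgrna,
            "n_detected": self.n_detected,
            "coverage": self.coverage,
            "n_reads_total": self.n_reads_total,
            "n_reads_unassigned": self.n_reads_unassigned,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def coverage_qc(
    counts: pd.Series,
    min_reads: int = 1,
    n_unassigned: int = 0,
) -> CoverageReport:
    """Coverage = fraction of guides with at least ``min_reads`` reads."""
    if len(counts) == 0:
        raise ValueError("coverage_qc: empty library/count vector")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    n_detected = int((arr >= min_reads).sum())
    return CoverageReport(
        n_sgrna=len(counts),
        n_detected=n_detected,
        coverage=n_detected / len(counts),
        n_reads_total=int(arr.sum()) + int(n_unassigned),
        n_reads_unassigned=int(n_unassigned),
        counts=counts,
    )
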
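"""sgRNA library model, generator, and CSV/FASTA I/O.

A pooled knockout library is an ordered collection of guide records, each
carrying a unique identifier, the symbol of the gene it targets (or a
reserved label for non-targeting controls), and its 20-nt spacer sequence.
The default configuration mirrors a genome-scale human knockout library:
19,050 targeted genes at 5-6 guides per gene plus 1,000 non-targeting
controls.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Reserved gene label identifying non-targeting control guides.
CONTROL_LABEL = "NonTargeting"

SPACER_LEN = 20
_BASES = np.array(list("ACGT"))

#: Default library geometry: genome-scale knockout library.
DEFAULT_N_GENES = 19_050
DEFAULT_PER_GENE_RANGE = (5, 6)
DEFAULT_N_CONTROLS = 1_000


class LibraryError(ValueError):
    """Raised when a library violates its structural invariants."""


@dataclass(frozen=True)
class SgRNARecord:
    """One guide: id, targeted gene (or control label), 20-nt spacer."""

    sgrna_id: str
    gene: str
    spacer: str

    @property
    def klass(self) -> str:
        return "control" if self.gene == CONTROL_LABEL else "targeting"

    def validate(self) -> None:
        if len(self.spacer) != SPACER_LEN or set(self.spacer) - set("ACGT"):
            raise LibraryError(
                f"sgRNA {self.sgrna_id!r}: spacer must be 20 nt over ACGT, "
                f"got {self.spacer!r}"
            )


@dataclass
class SgRNALibrary:
    """Ordered guide library with unique ids and unique spacers."""

    records: list[SgRNARecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        seen_ids: set[str] = set()
        seen_spacers: set[str] = set()
        for i, rec in enumerate(self.records):
            rec.validate()
            if rec.sgrna_id in seen_ids:
                raise LibraryError(f"row {i}: duplicate sgrna_id {rec.sgrna_id!r}")
            if rec.spacer in seen_spacers:
                raise LibraryError(f"row {i}: duplicate spacer {rec.spacer!r}")
            seen_ids.add(rec.sgrna_id)
            seen_spacers.add(rec.spacer)

    # -- views -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, SgRNALibrary) and self.records == other.records

    @property
    def sgrna_ids(self) -> list[str]:
        return [r.sgrna_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Distinct targeted gene symbols, in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.klass == "targeting" and r.gene not in seen:
                seen.add(r.gene)
                out.append(r.gene)
        return out

    @property
    def controls(self) -> list[SgRNARecord]:
        return [r for r in self.records if r.klass == "control"]

    def guides_of(self, gene: str) -> list[SgRNARecord]:
        found = [r for r in self.records if r.gene == gene]
        if not found:
            raise KeyError(f"gene {gene!r} not in library")
        return found

    def gene_of(self) -> dict[str, str]:
        """Map sgrna_id -> gene symbol (controls map to the control label)."""
        return {r.sgrna_id: r.gene for r in self.records}


def _random_spacers(n: int, rng: np.random.Generator, max_retries: int = 50) -> list[str]:
    """Draw ``n`` distinct random 20-mers.

    Collisions among random 20-mers are astronomically rare (4^20 ~ 1.1e12
    possibilities); retries exist only to make the contract airtight.
    """
    spacers: dict[str, None] = {}
    need = n
    for _ in range(max_retries):
        if need <= 0:
            break
        draw = rng.integers(0, 4, size=(need, SPACER_LEN))
        for row in draw:
            spacers.setdefault("".join(_BASES[row]), None)
        need = n - len(spacers)
    if len(spacers) < n:
        raise LibraryError(f"could not draw {n} distinct spacers")
    return list(spacers)[:n]


def generate_library(
    n_genes: int = DEFAULT_N_GENES,
    per_gene_range: tuple[int, int] = DEFAULT_PER_GENE_RANGE,
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int = 0,
    include_genes: Sequence[str] = (),
) -> SgRNALibrary:
    """Generate a random knockout library.

    Each of ``n_genes`` genes receives a guide count drawn uniformly from
    ``per_gene_range`` (inclusive); ``n_controls`` non-targeting controls are
    appended. Spacers are distinct random 20-mers. Deterministic under
    ``seed``.

    ``include_genes`` optionally replaces the first symbols of the generated
    gene list with caller-supplied names (e.g. genes to be planted as
    bypass hits downstream), leaving the geometry unchanged.
    """
    lo, hi = per_gene_range
    if n_genes < 0 or n_controls < 0:
        raise LibraryError("n_genes and n_controls must be non-negative")
    if not (1 <= lo <= hi):
        raise LibraryError(f"invalid per-gene range {per_gene_range}")
    if len(include_genes) > n_genes:
        raise LibraryError("more include_genes than genes requested")
    if len(set(include_genes)) != len(include_genes):
        raise LibraryError("include_genes contains duplicates")

    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    names = [f"GENE{i + 1:0{width}d}" for i in range(n_genes)]
    names[: len(include_genes)] = list(include_genes)

    per_gene = rng.integers(lo, hi + 1, size=n_genes)
    total = int(per_gene.sum()) + n_controls
    spacers = iter(_random_spacers(total, rng))

    records: list[SgRNARecord] = []
    for gene, k in zip(names, per_gene):
        for j in range(int(k)):
            records.append(
                SgRNARecord(f"{gene}_sg{j + 1}", gene, next(spacers))
            )
    for j in range(n_controls):
        records.append(
            SgRNARecord(f"CTRL_sg{j + 1}", CONTROL_LABEL, next(spacers))
        )
    return SgRNALibrary(records)


_HEADER = ["sgrna_id", "gene", "spacer", "klass"]


def write_library(lib: SgRNALibrary, path) -> None:
    """Write a library as UTF-8 comma-separated text with one header line."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for r in lib:
            w.writerow([r.sgrna_id, r.gene, r.spacer, r.klass])


def read_library(path) -> SgRNALibrary:
    """Read a library CSV written by :func:`write_library`.

    Raises :class:`LibraryError` naming the offending row on duplicate
    ids/spacers, malformed spacers, or a class label inconsistent with the
    gene column.
    """
    records: list[SgRNARecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _HEADER:
            raise LibraryError(f"{path}: expected header {','.join(_HEADER)}")
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LibraryError(f"{path} line {i}: expected 4 fields, got {len(row)}")
            sgrna_id, gene, spacer, klass = row
            rec = SgRNARecord(sgrna_id, gene, spacer)
            if rec.klass != klass:
                raise LibraryError(
                    f"{path} line {i}: klass {klass!r} inconsistent with gene {gene!r}"
                )
            records.append(rec)
    try:
        return SgRNALibrary(records)
    except LibraryError as err:
        raise LibraryError(f"{path}: {err}") from None


def write_spacers_fasta(lib: SgRNALibrary, path) -> None:
    """Export spacers as FASTA, one entry per guide (id as header)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in lib:
            fh.write(f">{r.sgrna_id}\n{r.spacer}\n")


def library_from_frame(ids: Iterable[str], genes: Iterable[str], spacers: Iterable[str]) -> SgRNALibrary:
    """Build a library from parallel columns (convenience for tests/IO)."""
    return SgRNALibrary([SgRNARecord(i, g, s) for i, g, s in zip(ids, genes, spacers)])
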
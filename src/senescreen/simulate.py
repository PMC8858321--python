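"""Forward simulator of the pooled bypass screen and the dose-response panel.

The screen model: a plasmid pool with lognormal representation skew is used
to infect a cell population at low multiplicity of infection (single
integration per infected cell). During drug selection, cells whose guide
knocked out a bypass gene keep dividing while the rest undergo a
near-complete proliferative arrest; growth is modelled as a deterministic
exponential expectation over the selection window, with stochasticity at
cell allocation and at sequencing (multinomial read sampling). The output
is a guide x sample count table with known ground truth, suitable for
end-to-end validation of the enrichment and hit-calling stages.

The panel model: per (cell line, drug), crystal-violet absorbance declines
with dose following a saturating Hill curve when the pair is truly
responsive, and stays flat otherwise, with additive Gaussian plate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .designs import DEFAULT_DOSES_UM
from .library import SgRNALibrary

ARMS = ("drug", "vehicle")
TIMEPOINTS = ("day0", "day14")


class SimulationError(ValueError):
    """Raised on invalid simulator configuration."""


@dataclass
class ScreenTruth:
    """Ground truth of a simulated bypass screen.

    Parameters
    ----------
    bypass_genes:
        Genes whose knockout lets cells escape the drug-imposed arrest.
    efficacy:
        Fraction of infected cells per guide with a functional knockout;
        either a single value applied to every guide or a map
        ``sgrna_id -> fraction``.
    r_bypass, r_arrest, r_untreated:
        Growth rates in divisions/day for bypass knockouts under drug,
        arrested cells under drug, and all cells in the vehicle arm.
        Defaults (0.8, 0.05, 1.0) give strong but not degenerate enrichment
        over the 14-day selection.
    """

    bypass_genes: frozenset[str] = frozenset()
    efficacy: float | Mapping[str, float] = 0.95
    r_bypass: float = 0.8
    r_arrest: float = 0.05
    r_untreated: float = 1.0
    duration_days: float = 14.0

    def __post_init__(self) -> None:
        self.bypass_genes = frozenset(self.bypass_genes)
        if self.duration_days <= 0:
            raise SimulationError("duration_days must be positive")
        if self.r_arrest > self.r_bypass:
            raise SimulationError("r_arrest must not exceed r_bypass")
        effs = (
            [self.efficacy]
            if np.isscalar(self.efficacy)
            else list(self.efficacy.values())
        )
        if any(not (0.0 <= e <= 1.0) for e in effs):
            raise SimulationError("efficacy values must lie in [0, 1]")

    def efficacy_vector(self, lib: SgRNALibrary) -> np.ndarray:
        if np.isscalar(self.efficacy):
            return np.full(len(lib), float(self.efficacy))
        return np.array([float(self.efficacy.get(r.sgrna_id, 0.0)) for r in lib])


@dataclass
class SimConfig:
    """Screen simulation settings.

    ``moi`` is recorded for provenance; at 0.2-0.5 essentially every
    infected cell carries a single integration, which is the regime the
    simulator models. ``n_cells`` defaults to 500 cells per library guide.
    Sequencing depth and infected-cell numbers are declared configuration,
    not facts of any particular experiment.
    """

    moi: float = 0.3
    n_cells: int | None = None
    plasmid_skew_sigma: float = 1.0
    depth_per_sgrna: float = 200.0
    n_replicates: int = 2
    include_vehicle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.moi):
            raise SimulationError("moi must be positive")
        if self.n_cells is not None and self.n_cells <= 0:
            raise SimulationError("n_cells must be positive")
        if self.plasmid_skew_sigma < 0:
            raise SimulationError("plasmid_skew_sigma must be non-negative")
        if self.depth_per_sgrna <= 0:
            raise SimulationError("depth_per_sgrna must be positive")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")

    def cells_for(self, lib: SgRNALibrary) -> int:
        return self.n_cells if self.n_cells is not None else 500 * len(lib)


def sample_name(arm: str, timepoint: str, replicate: int) -> str:
    return f"{arm}_{timepoint}_rep{replicate}"


def parse_sample(name: str) -> tuple[str, str, int]:
    """Parse ``{arm}_{timepoint}_rep{k}`` into its components."""
    arm, timepoint, rep = name.split("_")
    if arm not in ARMS or timepoint not in TIMEPOINTS or not rep.startswith("rep"):
        raise ValueError(f"malformed sample name {name!r}")
    return arm, timepoint, int(rep[3:])


def simulate_screen(
    lib: SgRNALibrary,
    truth: ScreenTruth,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate the pooled screen, returning (counts, truth).

    One plasmid pool (lognormal skew ``sigma``) is drawn per simulation and
    shared by all replicates, as a single amplified library infects every
    replicate; this also keeps replicate samples exchangeable under the
    null, which the permutation p-value method relies on. Per replicate:
    cells are allocated multinomially to guides, split deterministically
    into knockout/wild-type fractions by per-guide efficacy, grown
    exponentially for ``duration_days``, and sequenced by multinomial
    sampling at total depth ``depth_per_sgrna * len(lib)``.

    The returned frame is indexed by sgrna_id with columns
    ``{arm}_{timepoint}_rep{k}``; column sums equal the configured depth.
    """
    if len(lib) == 0:
        raise SimulationError("empty library")
    unknown = truth.bypass_genes - set(lib.genes)
    if unknown:
        raise SimulationError(f"bypass genes not in library: {sorted(unknown)}")
    n_cells = cfg.cells_for(lib)
    if n_cells <= 0:
        raise SimulationError("n_cells must be positive")

    rng = np.random.default_rng(cfg.seed)
    n = len(lib)
    depth = int(round(cfg.depth_per_sgrna * n))

    # Plasmid pool, shared across replicates.
    w = rng.lognormal(mean=0.0, sigma=cfg.plasmid_skew_sigma, size=n)
    w /= w.sum()

    genes = np.array([r.gene for r in lib])
    is_bypass = np.isin(genes, list(truth.bypass_genes))
    eff = truth.efficacy_vector(lib)
    d = truth.duration_days
    grow_ko_drug = np.where(is_bypass, 2.0 ** (truth.r_bypass * d), 2.0 ** (truth.r_arrest * d))
    grow_wt_drug = 2.0 ** (truth.r_arrest * d)
    grow_vehicle = 2.0 ** (truth.r_untreated * d)

    arms = ("drug", "vehicle") if cfg.include_vehicle else ("drug",)
    cols: dict[str, np.ndarray] = {}
    for rep in range(1, cfg.n_replicates + 1):
        cells = rng.multinomial(n_cells, w).astype(float)
        ko = cells * eff
        wt = cells - ko
        mass = {
            "drug": ko * grow_ko_drug + wt * grow_wt_drug,
            "vehicle": cells * grow_vehicle,
        }
        for arm in arms:
            cols[sample_name(arm, "day0", rep)] = rng.multinomial(
                depth, cells / cells.sum()
            )
            cols[sample_name(arm, "day14", rep)] = rng.multinomial(
                depth, mass[arm] / mass[arm].sum()
            )

    counts = pd.DataFrame(cols, index=pd.Index(lib.sgrna_ids, name="sgrna_id"))
    return counts, truth


# Constant 3' fill mimicking the invariant guide-scaffold sequence that
# follows the spacer in the sequenced amplicon.
SCAFFOLD_FILL = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
DEFAULT_ADAPTER = "TTGTGGAAAGGACGAAACACCG"


def emit_fastq(
    counts: pd.DataFrame,
    lib: SgRNALibrary,
    out_dir,
    adapter: str = DEFAULT_ADAPTER,
    read_len: int = 50,
    seed: int = 0,
) -> dict[str, str]:
    """Write one FASTQ file per sample column of ``counts``.

    Each count c for a guide yields c identical reads of the form
    ``adapter + spacer + constant 3' fill`` truncated to ``read_len``, with
    quality 'I' throughout; read order is shuffled deterministically under
    ``seed``. Returns a map sample name -> file path.
    """
    import os

    if read_len < len(adapter) + 20:
        raise SimulationError("read_len must cover adapter + 20-nt spacer")
    spacer_of = {r.sgrna_id: r.spacer for r in lib}
    missing = set(counts.index) - set(spacer_of)
    if missing:
        raise SimulationError(f"count rows not in library: {sorted(missing)[:3]}...")

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    qual = "I" * read_len
    paths: dict[str, str] = {}
    for col in counts.columns:
        seqs: list[str] = []
        for sg, c in counts[col].items():
            if c <= 0:
                continue
            full = adapter + spacer_of[sg] + SCAFFOLD_FILL
            full = (full + "A" * read_len)[:read_len]
            seqs.extend([full] * int(c))
        order = rng.permutation(len(seqs))
        path = os.path.join(out_dir, f"{col}.fastq")
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in enumerate(order):
                fh.write(f"@{col}_read{i}\n{seqs[j]}\n+\n{qual}\n")
        paths[col] = path
    return paths


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a count table as TSV (first column sgrna_id)."""
    counts.to_csv(path, sep="\t", index_label="sgrna_id")


def read_counts(path) -> pd.DataFrame:
    """Read a count table TSV written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    for col in df.columns:
        parse_sample(col)  # validate naming early
    return df


def simulate_panel(
    truth_map: Mapping[tuple[str, str], float],
    doses: tuple[float, ...] = DEFAULT_DOSES_UM,
    n_reps: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    baseline: float = 1.0,
    ec50_um: float = 1.0,
    hill: float = 1.0,
) -> pd.DataFrame:
    """Simulate the crystal-violet dose-response panel.

    ``truth_map`` assigns each (cell_line, drug) pair a fractional growth
    inhibition at saturating dose (0 for non-responsive pairs). Expected
    absorbance at dose d is ``baseline * (1 - effect * h(d))`` with
    ``h(d) = d^hill / (d^hill + ec50^hill)`` (a saturating, increasing
    function of log-dose; h(0) = 0 for the vehicle), plus additive Gaussian
    noise of standard deviation ``noise_sd * baseline``. Vehicle wells
    (dose 0) are included for every pair. Deterministic under ``seed``.
    """
    doses = tuple(float(d) for d in doses)
    if not doses:
        raise SimulationError("empty dose list")
    if any(d <= 0 for d in doses) or list(doses) != sorted(doses):
        raise SimulationError("doses must be positive and ascending")
    if n_reps < 2:
        raise SimulationError("need at least 2 replicates per dose")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, float, int, float]] = []
    for (line, drug), effect in truth_map.items():
        if not (0.0 <= effect <= 1.0):
            raise SimulationError(f"effect for {(line, drug)} outside [0, 1]")
        for dose in (0.0,) + doses:
            h = 0.0 if dose == 0.0 else dose**hill / (dose**hill + ec50_um**hill)
            mu = baseline * (1.0 - effect * h)
            for rep in range(1, n_reps + 1):
                ab = mu + rng.normal(0.0, noise_sd * baseline)
                rows.append((line, drug, dose, rep, ab))
    return pd.DataFrame(
        rows, columns=["cell_line", "drug", "dose_uM", "replicate", "absorbance"]
    )
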
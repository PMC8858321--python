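"""Default study designs for recovery experiments.

These constants encode the configurations used by the recovery experiments
that the simulator supports: the 18-gene bypass candidate list nominated by
the genome-wide screen, and the 22-cell-line CDK4/6-inhibitor panel with its
primary- and secondary-screen ground truth.

Only four of the 18 candidate genes are publicly named (F9, PROZ, LPAR5 and
MOGAT, the genes for which validation guides were designed); the remaining
14 symbols here (``BYP05`` .. ``BYP18``) are synthetic placeholders standing
in for the unnamed candidates. Likewise, 14 of the 22 panel cell lines carry
their real names and the remaining 8 are synthetic placeholder lines.
"""

from __future__ import annotations

#: 18 bypass candidate genes: 4 named + 14 synthetic placeholders.
CANDIDATE_GENES: tuple[str, ...] = (
    "F9",
    "PROZ",
    "LPAR5",
    "MOGAT",
) + tuple(f"BYP{i:02d}" for i in range(5, 19))

#: The three CDK4/6 inhibitors of the dose-response panel.
DRUGS: tuple[str, ...] = ("Palbociclib", "Abemaciclib", "Ribociclib")

#: Default dose ladder in uM (0 denotes the DMSO vehicle).
DEFAULT_DOSES_UM: tuple[float, ...] = (0.25, 1.0, 5.0)

#: 22 panel cell lines; the last 8 are synthetic placeholders.
PANEL_LINES: tuple[str, ...] = (
    "MCF7",
    "SKMEL28",
    "ACHN",
    "HT-29",
    "SNU-387",
    "T47D",
    "HCT-116",
    "A549",
    "MDA-MB-468",
    "SK-OV-3",
    "Capan2",
    "NCI-H23",
    "OVCAR-3",
    "PC-3",
) + tuple(f"LINE-{i:02d}" for i in range(15, 23))

#: Cell lines confirmed as responders in the secondary screen.
CONFIRMED_LINES: tuple[str, ...] = ("MCF7", "SKMEL28", "ACHN", "HT-29", "SNU-387")

#: Primary responders that failed secondary confirmation.
UNCONFIRMED_PRIMARY_LINES: tuple[str, ...] = ("T47D", "HCT-116", "A549")

#: All 8 primary-screen responder lines.
PRIMARY_RESPONDER_LINES: tuple[str, ...] = CONFIRMED_LINES + UNCONFIRMED_PRIMARY_LINES


def primary_panel_truth(effect: float = 0.6) -> dict[tuple[str, str], float]:
    """Ground-truth effect sizes for the primary 22-line x 3-drug panel.

    Confirmed responders are responsive to all three inhibitors; the three
    primary-only responders to two (Palbociclib and Abemaciclib, the two
    drugs with the strongest arrest in the validation experiments); all
    other (line, drug) pairs are non-responsive (effect 0).
    """
    truth = {(line, drug): 0.0 for line in PANEL_LINES for drug in DRUGS}
    for line in CONFIRMED_LINES:
        for drug in DRUGS:
            truth[(line, drug)] = effect
    for line in UNCONFIRMED_PRIMARY_LINES:
        truth[(line, "Palbociclib")] = effect
        truth[(line, "Abemaciclib")] = effect
    return truth


def secondary_panel_truth(effect: float = 0.6) -> dict[tuple[str, str], float]:
    """Ground truth for the secondary screen, restricted to primary responders.

    The five confirmed lines keep their responsiveness; the three
    unconfirmed lines are non-responsive on re-evaluation.
    """
    truth = {
        (line, drug): 0.0 for line in PRIMARY_RESPONDER_LINES for drug in DRUGS
    }
    for line in CONFIRMED_LINES:
        for drug in DRUGS:
            truth[(line, drug)] = effect
    return truth
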
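"""Default targeted panel for the preeclampsia urine workflows.

The package ships the 21-protein urinary panel (UniProt accession, gene
symbol) monitored in the targeted validation and longitudinal stages,
together with the observed PE/CTL group-mean intensity ratios at each
stage.  The packaged simulation workflows plant ``log2(ratio)`` as the
case effect for each protein, so synthetic cohorts reproduce the panel's
effect-size structure; all downstream numbers are then re-computed from
the simulated data, never read off these tables.

BTD (biotinidase, P43251) is the endogenous reference protein used to
correct for protein-loading (Bradford) variation; it is stable between
case and control urine and is therefore not part of the comparison panel.
"""

from __future__ import annotations

# accession -> (gene, validation-stage PE/CTL ratio)
VALIDATION_PANEL: dict[str, tuple[str, float]] = {
    "P04217": ("A1BG", 4.85),
    "P43652": ("AFM", 6.89),
    "P25311": ("AZGP1", 14.39),
    "P01024": ("C3", 1.92),
    "P00915": ("CA1", 6.20),
    "P00450": ("CP", 6.55),
    "P02774": ("GC", 11.31),
    "P19823": ("ITIH2", 6.35),
    "P02763": ("ORM1", 2.96),
    "P19652": ("ORM2", 1.66),
    "P01009": ("SERPINA1", 9.50),
    "P01011": ("SERPINA3", 3.83),
    "P08185": ("SERPINA6", 2.27),
    "P05543": ("SERPINA7", 16.42),
    "P01008": ("SERPINC1", 4.38),
    "I3L145": ("SHBG", 4.35),
    "P02766": ("TTR", 4.32),
    "P02768": ("ALB", 2.57),
    "P69905": ("HBA1", 3.74),
    "P68871": ("HBB", 24.62),
    "P02787": ("TF", 2.82),
}

# gene -> (PE/CTL ratio at 20-24 weeks, PE/CTL ratio at 30-34 weeks)
LONGITUDINAL_RATIOS: dict[str, tuple[float, float]] = {
    "SERPINA7": (1.42, 1.62),
    "CP": (1.81, 4.87),
    "AFM": (1.29, 2.48),
    "ITIH2": (1.14, 3.67),
    "TF": (1.86, 8.42),
    "A1BG": (1.19, 2.22),
    "SERPINA3": (1.39, 1.95),
    "GC": (1.20, 1.97),
    "ALB": (1.49, 5.54),
    "SERPINA1": (1.36, 4.11),
    "C3": (1.07, 1.63),
    "ORM1": (1.69, 2.52),
    "SERPINA6": (1.05, 1.97),
    "ORM2": (1.35, 1.52),
    "TTR": (1.23, 1.48),
    "HBA1": (5.27, 55.40),
    "HBB": (5.43, 30.91),
    "SERPINC1": (0.99, 1.28),
    "AZGP1": (1.44, 1.19),
    "CA1": (0.62, 0.70),
    "SHBG": (0.92, 1.07),
}

REFERENCE_PROTEIN = "P43251"  # biotinidase (BTD)
REFERENCE_GENE = "BTD"

GENE_TO_ACCESSION: dict[str, str] = {
    gene: acc for acc, (gene, _) in VALIDATION_PANEL.items()
}

# Screening markers evaluated by ROC in the longitudinal stage.
SCREENING_MARKERS: tuple[str, ...] = ("CP", "SERPINA7")
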
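"""Published measurements from the Holstein HED case study.

These are the printed input values of the reported case — a female
Holstein calf with generalized hypohidrotic ectodermal dysplasia caused
by a de novo 3.8-Mb X-chromosome inversion disrupting EDA and XIST —
used as worked-example inputs and as defaults for the synthetic-data
generators.  They are inputs (measurements and coordinates), not
precomputed results.
"""

from __future__ import annotations

import pandas as pd

from .breakpoints import Breakpoint

#: per-quadrat morphometry of frontal skin (three 1-mm^2 quadrats per animal)
CASE_QUADRATS = pd.DataFrame(
    [
        ("control", 1, 9, 89.9, 59_689),
        ("control", 2, 10, 85.1, 59_274),
        ("control", 3, 9, 86.6, 56_286),
        ("affected", 1, 43, 22.9, 18_802),
        ("affected", 2, 44, 23.8, 20_348),
        ("affected", 3, 56, 18.0, 14_773),
    ],
    columns=["group", "quadrat_id", "hair_count", "mean_diameter_um",
             "total_area_um2"],
)

#: inversion breakpoints on chromosome X (UMD3.1), stored as the last
#: reference base before each break
BREAKPOINT_XIST = Breakpoint(chrom="X", left_pos=82_271_052)
BREAKPOINT_EDA = Breakpoint(chrom="X", left_pos=86_034_441)

#: 12-bp segment partially duplicated at the first breakpoint junction
MICROHOMOLOGY_MOTIF = "GTACAAGAAACT"

#: centromeric satellite repeat region masked in depth analyses
#: (1-based inclusive)
DEPTH_MASK = [(83_151_156, 83_181_156)]

#: average whole-genome sequence coverage of the case genome
MEAN_COVERAGE = 13.8

#: case-study pedigree statistics
CASE_INBREEDING = 0.0458
COHORT_INBREEDING = 0.0459
N_LOOP_ANCESTORS = 10
EXPECTED_CASES_RANGE = (10, 38_529)
CASE_BIRTH_YEAR = 2014
OBSERVATION_YEARS = (2002, 2017)

#: sire-progeny mortality (0-6 months, natural deaths) vs population
SIRE_MORTALITY = 0.1022
POPULATION_MORTALITY = 0.1093
POPULATION_MORTALITY_SD = 0.0021
N_POPULATION_SIRES = 3577
MIN_DESCENDANTS = 100

#: variant-filter outcome scale in the case genome
N_PRIVATE_HET = 5382
N_PROTEIN_ALTERING = 9
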
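import math

import pytest

from karyohybrid.karyotype import (
    ChromosomeMeasurement,
    ChromosomeRecord,
    arm_ratio,
    classify_chromosome,
)

# the four study karyotypes: formula counts and printed L/S ratios
STUDY_KARYOTYPES = {
    "L_radiata": ({"t": 10, "st": 12}, 1.73, "4A"),
    "L_aurea": ({"m": 8, "T": 6}, 2.45, "2B"),
    "hybrid1": ({"m": 4, "st": 6, "t": 5, "T": 3}, 3.50, "3B"),
    "hybrid2": ({"m": 4, "st": 6, "t": 5, "T": 3}, 4.31, "3C"),
}


def make_records(arms, taxon="test"):
    """Build ChromosomeRecords from a list of (short, long) arm pairs."""
    haploid = sum(s + l for s, l in arms) / 2.0
    records = []
    for i, (s, l) in enumerate(arms):
        meas = ChromosomeMeasurement(taxon, "c1", i + 1, min(s, l), max(s, l))
        records.append(
            ChromosomeRecord(
                measurement=meas,
                total_length=s + l,
                arm_ratio=arm_ratio(s, l),
                type_class=classify_chromosome(s, l),
                relative_length=100.0 * (s + l) / haploid,
            )
        )
    return records


@pytest.fixture
def study_karyotypes():
    return STUDY_KARYOTYPES
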
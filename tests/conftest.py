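"""Shared fixtures: printed combination-table counts and cohort builders.

The count tables below are the published combination tables used as fixed
inputs; every OR/p expectation in the suite is either computed from them by
an independent oracle or verified arithmetic.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from polyassoc import CohortDataset, DEFAULT_PANEL, Subject

# combination label tuple -> {group: count}
TABLE4_SNPS = ("rs4072037", "rs9841504")  # MUC1 x ZBTB20, all cases vs controls
TABLE4 = {
    ("GA", "GG"): {"all-cases": 12, "controls": 29},
    ("GA", "GC"): {"all-cases": 7, "controls": 5},
    ("AA", "GG"): {"all-cases": 69, "controls": 57},
    ("AA", "GC"): {"all-cases": 23, "controls": 9},
}

TABLE5_SNPS = ("rs2274223", "rs13361707")  # PLCE1 x PRKAA1
TABLE5 = {
    ("AA", "AA"): {"hereditary-cases": 7, "non-hereditary-cases": 11, "controls": 18},
    ("AA", "GA"): {"hereditary-cases": 19, "non-hereditary-cases": 17, "controls": 33},
    ("AG", "AA"): {"hereditary-cases": 6, "non-hereditary-cases": 2, "controls": 7},
    ("AG", "GA"): {"hereditary-cases": 19, "non-hereditary-cases": 4, "controls": 16},
}

TABLE6_SNPS = ("rs4072037", "rs9841504", "rs2790")  # MUC1 x ZBTB20 x TYMS
TABLE6 = {
    ("GA", "GG", "AA"): {"all-cases": 3, "controls": 9},
    ("AA", "GG", "AA"): {"all-cases": 24, "controls": 26},
    ("AA", "GG", "AG"): {"all-cases": 36, "controls": 22},
    ("AA", "GC", "AA"): {"all-cases": 9, "controls": 4},
    ("AA", "GC", "AG"): {"all-cases": 11, "controls": 4},
}

_PANEL_BY_RS = {s.rs_id: s for s in DEFAULT_PANEL}


def cohort_from_combo_counts(rs_ids, rows) -> CohortDataset:
    """Build a cohort whose genotype combinations over ``rs_ids`` reproduce
    the given per-group counts; the other panel SNPs are left missing."""
    snps = DEFAULT_PANEL
    cols = {rs: i for i, rs in enumerate(s.rs_id for s in snps)}
    subjects, genotypes = [], []
    counter = itertools.count()
    for labels, groups in rows.items():
        for group, count in groups.items():
            for _ in range(count):
                k = next(counter)
                if group == "controls":
                    status, hered = "control", "na"
                elif group == "hereditary-cases":
                    status, hered = "case", "yes"
                elif group == "non-hereditary-cases":
                    status, hered = "case", "no"
                else:  # all-cases: hereditary flag irrelevant, mark "no"
                    status, hered = "case", "no"
                subjects.append(
                    Subject(
                        id=f"s{k:04d}",
                        status=status,
                        sex="M" if k % 2 else "F",
                        age=30 + (k % 19),
                        hereditary=hered,
                    )
                )
                row = [None] * len(snps)
                for rs, g in zip(rs_ids, labels):
                    row[cols[rs]] = "".join(sorted(g))
                genotypes.append(row)
    return CohortDataset(snps, subjects, np.array(genotypes, dtype=object))


@pytest.fixture(scope="session")
def table4_cohort() -> CohortDataset:
    return cohort_from_combo_counts(TABLE4_SNPS, TABLE4)


@pytest.fixture(scope="session")
def table5_cohort() -> CohortDataset:
    return cohort_from_combo_counts(TABLE5_SNPS, TABLE5)


@pytest.fixture(scope="session")
def table6_cohort() -> CohortDataset:
    return cohort_from_combo_counts(TABLE6_SNPS, TABLE6)


@pytest.fixture()
def tiny_cohort() -> CohortDataset:
    """Three fully-genotyped subjects across the whole panel."""
    subjects = (
        Subject("a1", "case", "M", 35, "yes", "cardia", "diffuse"),
        Subject("a2", "case", "F", 42, "no", "noncardia", "intestinal"),
        Subject("c1", "control", "M", 38),
    )
    genotypes = np.array(
        [
            ["AA", "CG", "CT", "AG", "AG", "AG"],
            ["AG", "GG", "CC", "AA", "AA", "AA"],
            ["GG", "GG", "CT", "AG", "GG", "GG"],
        ],
        dtype=object,
    )
    return CohortDataset(DEFAULT_PANEL, subjects, genotypes)
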
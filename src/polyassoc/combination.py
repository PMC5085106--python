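"""Combined-genotype risk stratification.

Cross-classifies subjects by their genotype tuple over a chosen SNP subset,
picks a reference stratum, and reports per-stratum counts and unadjusted
odds ratios (cross-product, Woolf CI, uncorrected chi-square p) against one
or more comparison groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import (
    AssociationResult,
    ComparisonDesign,
    ContingencyTable,
    STANDARD_DESIGNS,
    odds_ratio,
)
from .errors import ValidationError
from .genotype_data import MISSING, CohortDataset, dose_matrix

#: Strata with any group count below this get counts but no OR.  The value
#: is the smallest group count printed alongside an OR in the reference
#: combination tables.
DEFAULT_MIN_COUNT = 2


@dataclass
class StratumResult:
    """One row of a combination table."""

    labels: tuple[str, ...]  # genotype label per SNP, panel display order
    dose_total: int  # summed risk-allele dose of the combination
    counts: dict[str, int]  # group name -> subject count
    percents: dict[str, float]  # group name -> % of group's complete-case total
    ors: dict[str, AssociationResult | None]  # comparison name -> OR (None = filtered)
    is_reference: bool = False

    @property
    def label(self) -> str:
        return "-".join(self.labels)


def _design_name(design: ComparisonDesign) -> str:
    for name, d in STANDARD_DESIGNS.items():
        if d == design:
            return name
    return f"{design.group1}-vs-{design.group2}"


def combine(
    ds: CohortDataset,
    snps: Sequence[str],
    reference: str | Sequence[str] = "lowest-dose-observed",
    min_count: int = DEFAULT_MIN_COUNT,
    comparisons: Sequence[ComparisonDesign | str] = ("cases-vs-controls",),
) -> list[StratumResult]:
    """Enumerate observed genotype combinations and their odds ratios.

    Only combinations observed in the data appear.  The reference stratum is
    the observed combination with the lowest summed risk-allele dose
    (lexicographic label as tie-break), or an explicit label tuple.  Each
    comparison contributes an unadjusted OR versus the reference; strata
    with any group count below ``min_count`` keep their counts but drop the
    OR.  Percentages are within-group over the complete-case total.
    """
    if len(set(snps)) != len(snps):
        raise ValidationError("duplicate rs ids in combination request")
    if not 2 <= len(snps) <= ds.n_snps:
        if len(snps) != 1:  # single-SNP degenerates to codominant; allowed
            raise ValidationError("need between 1 SNP and the panel size")
    designs = [
        STANDARD_DESIGNS[c] if isinstance(c, str) else c for c in comparisons
    ]
    comp_names = [_design_name(d) for d in designs]
    cols = [ds.snp_index(rs) for rs in snps]
    snp_defs = [ds.snps[j] for j in cols]
    doses = dose_matrix(ds)[:, cols]
    complete = (doses != MISSING).all(axis=1)

    group_names: list[str] = []
    for d in designs:
        for g in (d.group1, d.group2):
            if g not in group_names:
                group_names.append(g)
    group_masks = {g: ds.status_mask(g) & complete for g in group_names}
    group_totals = {g: int(m.sum()) for g, m in group_masks.items()}

    # observed combinations among subjects relevant to any comparison
    relevant = np.zeros(ds.n_subjects, dtype=bool)
    for m in group_masks.values():
        relevant |= m
    combos: dict[tuple[int, ...], dict[str, int]] = {}
    for i in np.flatnonzero(relevant):
        key = tuple(int(x) for x in doses[i])
        rec = combos.setdefault(key, {g: 0 for g in group_names})
        for g, m in group_masks.items():
            if m[i]:
                rec[g] += 1

    def labels_of(key: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(sd.label_for_dose(d) for sd, d in zip(snp_defs, key))

    if reference == "lowest-dose-observed":
        ref_key = min(combos, key=lambda k: (sum(k), labels_of(k)))
    else:
        wanted = tuple(reference)
        matches = [k for k in combos if labels_of(k) == wanted]
        if not matches:
            observed = sorted("-".join(labels_of(k)) for k in combos)
            raise ValidationError(
                f"reference {'-'.join(wanted)} not observed; observed "
                f"combinations: {', '.join(observed)}"
            )
        ref_key = matches[0]

    results: list[StratumResult] = []
    ref_counts = combos[ref_key]
    for key in sorted(combos, key=lambda k: (sum(k), labels_of(k))):
        counts = combos[key]
        percents = {
            g: 100.0 * counts[g] / group_totals[g] if group_totals[g] else float("nan")
            for g in group_names
        }
        ors: dict[str, AssociationResult | None] = {}
        if key != ref_key:
            for name, d in zip(comp_names, designs):
                quad = (
                    counts[d.group1],
                    ref_counts[d.group1],
                    counts[d.group2],
                    ref_counts[d.group2],
                )
                if counts[d.group1] < min_count or counts[d.group2] < min_count:
                    ors[name] = None
                    continue
                table = ContingencyTable(*quad)
                correction = "haldane" if 0 in quad else "none"
                res = odds_ratio(table, correction=correction)
                res.model = "combined-genotype"
                ors[name] = res
        results.append(
            StratumResult(
                labels=labels_of(key),
                dose_total=sum(key),
                counts=dict(counts),
                percents=percents,
                ors=ors,
                is_reference=key == ref_key,
            )
        )
    return results


def risk_ladder(
    results: Sequence[StratumResult], by: str
) -> list[tuple[str, float, str]]:
    """Strata ordered by ascending OR for one comparison.

    Returns (combination label, OR, fold annotation) triples, reference
    first with OR 1.  Emits a warning (not an error) when the OR order
    disagrees with the risk-allele dose order — observed tables do show
    such non-monotonicity.
    """
    entries = []
    for r in results:
        if r.is_reference:
            entries.append((r.label, 1.0, "reference", r.dose_total))
        elif r.ors.get(by) is not None:
            o = r.ors[by].or_point
            entries.append((r.label, o, f"{o:.1f}-fold", r.dose_total))
    if not any(not e[2] == "reference" for e in entries):
        raise ValidationError("no non-reference stratum carries an OR")
    entries.sort(key=lambda e: e[1])
    dose_order = [e[3] for e in entries]
    if dose_order != sorted(dose_order):
        warnings.warn(
            "stratum OR order disagrees with risk-allele dose order",
            stacklevel=2,
        )
    return [(label, o, ann) for label, o, ann, _ in entries]
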
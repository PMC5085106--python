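"""Data model and I/O for subject-level case-control genotype data.

The canonical on-disk format is a TSV with the phenotype columns
``id  status  sex  age  hereditary  location  lauren`` followed by one
two-letter genotype column per SNP ("00"/"NN" for missing).  SNP metadata
(gene label, alleles, risk allele) travels in ``#snp`` comment lines so
that ``read_cohort(write_cohort(ds))`` is the identity.  A PLINK-style
.ped/.map dialect is supported read-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ParseError, ValidationError

#: Sentinel for a missing genotype in a dose matrix.
MISSING: int = -1

_STATUSES = {"case", "control"}
_SEXES = {"M", "F"}
_HEREDITARY = {"yes", "no", "na"}
_LOCATIONS = {"cardia", "noncardia", "unknown"}
_LAUREN = {"intestinal", "diffuse", "mixed", "unknown"}
_MISSING_GT = {"00", "NN", "--", ".."}

PHENOTYPE_COLUMNS = ("id", "status", "sex", "age", "hereditary", "location", "lauren")


@dataclass(frozen=True)
class SnpDef:
    """Identity of one biallelic SNP in the panel.

    ``allele_a``/``allele_b`` follow the display order used in combination
    labels (heterozygote printed as ``allele_a + allele_b``); ``risk_allele``
    is ``None`` until set explicitly or via :func:`assign_risk_alleles`.
    """

    rs_id: str
    gene_label: str
    allele_a: str
    allele_b: str
    risk_allele: str | None = None

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.rs_id}: alleles must differ")
        if self.risk_allele is not None and self.risk_allele not in (
            self.allele_a,
            self.allele_b,
        ):
            raise ValidationError(
                f"{self.rs_id}: risk allele {self.risk_allele!r} is not one of "
                f"{self.allele_a}/{self.allele_b}"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_a, self.allele_b))

    def dose(self, genotype: str | None) -> int:
        """Risk-allele count of a normalized genotype string (MISSING if absent)."""
        if genotype is None:
            return MISSING
        if self.risk_allele is None:
            raise ConfigurationError(
                f"{self.rs_id}: risk allele unset; call assign_risk_alleles first"
            )
        return genotype.count(self.risk_allele)

    def label_for_dose(self, dose: int) -> str:
        """Genotype label in panel display order for a given risk-allele dose."""
        if self.risk_allele is None:
            raise ConfigurationError(f"{self.rs_id}: risk allele unset")
        other = self.allele_b if self.risk_allele == self.allele_a else self.allele_a
        if dose == 0:
            return other * 2
        if dose == 2:
            return self.risk_allele * 2
        return self.allele_a + self.allele_b


#: The six-SNP panel used throughout; risk alleles follow the combination
#: tables' genotype orderings and are overridable per analysis.
DEFAULT_PANEL: tuple[SnpDef, ...] = (
    SnpDef("rs4072037", "MUC1", "G", "A", "A"),
    SnpDef("rs9841504", "ZBTB20", "G", "C", "C"),
    SnpDef("rs2294008", "PSCA", "C", "T", "T"),
    SnpDef("rs2274223", "PLCE1", "A", "G", "G"),
    SnpDef("rs13361707", "PTGER4/PRKAA1", "G", "A", "G"),
    SnpDef("rs2790", "TYMS", "A", "G", "G"),
)


@dataclass(frozen=True)
class Subject:
    id: str
    status: str
    sex: str
    age: int
    hereditary: str = "na"
    location: str = "unknown"
    lauren: str = "unknown"

    def __post_init__(self):
        if self.status not in _STATUSES:
            raise ValidationError(f"{self.id}: bad status {self.status!r}")
        if self.sex not in _SEXES:
            raise ValidationError(f"{self.id}: bad sex {self.sex!r}")
        if self.hereditary not in _HEREDITARY:
            raise ValidationError(f"{self.id}: bad hereditary flag {self.hereditary!r}")
        if self.location not in _LOCATIONS:
            raise ValidationError(f"{self.id}: bad location {self.location!r}")
        if self.lauren not in _LAUREN:
            raise ValidationError(f"{self.id}: bad Lauren type {self.lauren!r}")
        if self.status == "control" and (
            self.hereditary != "na"
            or self.location != "unknown"
            or self.lauren != "unknown"
        ):
            raise ValidationError(
                f"{self.id}: controls must have hereditary=na and "
                "location=lauren=unknown"
            )
        if self.status == "case" and self.hereditary == "na":
            raise ValidationError(f"{self.id}: cases need a yes/no hereditary flag")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


def _normalize_genotype(raw: str, snp: SnpDef, subject_id: str) -> str | None:
    raw = raw.strip()
    if raw in _MISSING_GT or raw == "":
        return None
    if len(raw) != 2:
        raise ValidationError(
            f"subject {subject_id}, {snp.rs_id}: genotype {raw!r} is not a "
            "two-letter allele pair"
        )
    for allele in raw:
        if allele not in snp.alleles:
            raise ValidationError(
                f"subject {subject_id}, {snp.rs_id}: allele {allele!r} not in "
                f"{snp.allele_a}/{snp.allele_b}"
            )
    # unphased: store alphabetically so "GA" == "AG"
    return "".join(sorted(raw))


@dataclass
class CohortDataset:
    """Subjects x SNPs genotype container backing every analysis."""

    snps: tuple[SnpDef, ...]
    subjects: tuple[Subject, ...]
    genotypes: np.ndarray  # object array of normalized strings / None
    age_window: tuple[int, int] = (0, 49)

    def __post_init__(self):
        self.snps = tuple(self.snps)
        self.subjects = tuple(self.subjects)
        self.genotypes = np.asarray(self.genotypes, dtype=object)
        if self.genotypes.shape != (len(self.subjects), len(self.snps)):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} != "
                f"({len(self.subjects)}, {len(self.snps)})"
            )
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject id(s): {', '.join(dup)}")
        rs = [s.rs_id for s in self.snps]
        if len(set(rs)) != len(rs):
            raise ValidationError("duplicate rs ids in panel")
        lo, hi = self.age_window
        for s in self.subjects:
            if not (lo <= s.age <= hi):
                raise ValidationError(
                    f"{s.id}: age {s.age} outside inclusion window [{lo}, {hi}]"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, rs_id: str) -> int:
        for i, s in enumerate(self.snps):
            if s.rs_id == rs_id:
                return i
        raise ValidationError(f"unknown SNP {rs_id!r}")

    def missingness(self) -> dict[str, float]:
        """Per-SNP missing-genotype rate."""
        out = {}
        for j, snp in enumerate(self.snps):
            col = self.genotypes[:, j]
            out[snp.rs_id] = float(sum(g is None for g in col)) / max(len(col), 1)
        return out

    def subset(self, mask: Sequence[bool]) -> "CohortDataset":
        mask = np.asarray(mask, dtype=bool)
        return CohortDataset(
            self.snps,
            tuple(s for s, m in zip(self.subjects, mask) if m),
            self.genotypes[mask],
            self.age_window,
        )

    def status_mask(self, group: str) -> np.ndarray:
        """Boolean mask for a named comparison group."""
        if group == "all-cases":
            return np.array([s.is_case for s in self.subjects])
        if group == "hereditary-cases":
            return np.array(
                [s.is_case and s.hereditary == "yes" for s in self.subjects]
            )
        if group == "non-hereditary-cases":
            return np.array([s.is_case and s.hereditary == "no" for s in self.subjects])
        if group == "controls":
            return np.array([not s.is_case for s in self.subjects])
        raise ValidationError(f"unknown group {group!r}")


def dose_matrix(ds: CohortDataset) -> np.ndarray:
    """Subjects x SNPs risk-allele counts; ``MISSING`` (-1) where ungenotyped."""
    for snp in ds.snps:
        if snp.risk_allele is None:
            raise ConfigurationError(
                f"{snp.rs_id}: risk allele unset; call assign_risk_alleles first"
            )
    out = np.full((ds.n_subjects, ds.n_snps), MISSING, dtype=np.int64)
    for j, snp in enumerate(ds.snps):
        for i, g in enumerate(ds.genotypes[:, j]):
            if g is not None:
                out[i, j] = g.count(snp.risk_allele)
    return out


def assign_risk_alleles(
    ds: CohortDataset,
    rule: str = "minor-in-controls",
    fixed_map: Mapping[str, str] | None = None,
) -> CohortDataset:
    """Return a dataset whose SNPs all carry a risk allele.

    ``minor-in-controls`` takes the minor allele among genotyped controls,
    breaking exact 50% ties by lexicographic order (with a warning);
    ``fixed-map`` applies a user map verbatim.
    """
    if rule not in ("minor-in-controls", "fixed-map"):
        raise ValidationError(f"unknown rule {rule!r}")
    if rule == "fixed-map":
        if not fixed_map:
            raise ValidationError("fixed-map rule requires a fixed_map argument")
        new_snps = []
        for snp in ds.snps:
            allele = fixed_map.get(snp.rs_id, snp.risk_allele)
            if allele is not None and allele not in snp.alleles:
                raise ValidationError(
                    f"{snp.rs_id}: fixed-map allele {allele!r} not in "
                    f"{snp.allele_a}/{snp.allele_b}"
                )
            new_snps.append(replace(snp, risk_allele=allele))
        return CohortDataset(new_snps, ds.subjects, ds.genotypes, ds.age_window)

    control_mask = ds.status_mask("controls")
    new_snps = []
    for j, snp in enumerate(ds.snps):
        col = [g for g, m in zip(ds.genotypes[:, j], control_mask) if m and g]
        if not col:
            raise ValidationError(
                f"{snp.rs_id}: no genotyped controls for minor-in-controls rule"
            )
        n_a = sum(g.count(snp.allele_a) for g in col)
        total = 2 * len(col)
        freq_a = n_a / total
        if freq_a == 0.5:
            minor = min(snp.allele_a, snp.allele_b)
            warnings.warn(
                f"{snp.rs_id}: control allele frequencies tied at 0.5; "
                f"choosing {minor!r} lexicographically",
                stacklevel=2,
            )
        else:
            minor = snp.allele_a if freq_a < 0.5 else snp.allele_b
        new_snps.append(replace(snp, risk_allele=minor))
    return CohortDataset(new_snps, ds.subjects, ds.genotypes, ds.age_window)


# ---------------------------------------------------------------------------
# TSV reader / writer

_HERED_OUT = {"yes": "1", "no": "0", "na": "NA"}
_HERED_IN = {"1": "yes", "0": "no", "NA": "na", "yes": "yes", "no": "no", "na": "na"}


def write_cohort(ds: CohortDataset, path: str | Path) -> None:
    """Write the canonical TSV, including ``#snp`` metadata comment lines."""
    path = Path(path)
    lines = []
    for snp in ds.snps:
        risk = snp.risk_allele or "unset"
        lines.append(
            f"#snp\t{snp.rs_id}\t{snp.gene_label}\t{snp.allele_a}\t"
            f"{snp.allele_b}\t{risk}"
        )
    lines.append(f"#age_window\t{ds.age_window[0]}\t{ds.age_window[1]}")
    lines.append("\t".join(PHENOTYPE_COLUMNS + tuple(s.rs_id for s in ds.snps)))
    for i, subj in enumerate(ds.subjects):
        loc = "NA" if subj.status == "control" else subj.location
        lau = "NA" if subj.status == "control" else subj.lauren
        row = [
            subj.id,
            subj.status,
            subj.sex,
            str(subj.age),
            _HERED_OUT[subj.hereditary],
            loc,
            lau,
        ]
        for j, snp in enumerate(ds.snps):
            g = ds.genotypes[i, j]
            row.append("00" if g is None else _display_genotype(g, snp))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _display_genotype(normalized: str, snp: SnpDef) -> str:
    if normalized[0] != normalized[1]:
        return snp.allele_a + snp.allele_b
    return normalized


def _subject_from_fields(
    fields: Sequence[str], line_no: int
) -> Subject:
    if len(fields) < len(PHENOTYPE_COLUMNS):
        raise ParseError(
            f"expected at least {len(PHENOTYPE_COLUMNS)} phenotype fields, "
            f"got {len(fields)}",
            line=line_no,
        )
    sid, status, sex, age, hered, loc, lauren = fields[:7]
    try:
        age_i = int(age)
    except ValueError:
        raise ParseError(f"subject {sid}: non-integer age {age!r}", line=line_no)
    if hered not in _HERED_IN:
        raise ParseError(f"subject {sid}: bad hereditary field {hered!r}", line=line_no)
    loc = "unknown" if loc in ("NA", "") else loc
    lauren = "unknown" if lauren in ("NA", "") else lauren
    return Subject(sid, status, sex, age_i, _HERED_IN[hered], loc, lauren)


def read_cohort(
    path: str | Path,
    format: str = "tsv",
    panel: Sequence[SnpDef] | None = None,
    age_window: tuple[int, int] | None = None,
) -> CohortDataset:
    """Read a cohort from TSV or a PLINK-style ped/map pair.

    For ``format="ped-map"`` pass the .ped path; the .map is found by
    extension swap.  ``panel`` supplies SNP metadata when the file carries
    none (TSV ``#snp`` lines win when present); unknown rs ids fall back to
    :data:`DEFAULT_PANEL` and finally to alleles inferred from the data.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "tsv":
        return _read_tsv(path, panel, age_window)
    if format == "ped-map":
        return _read_ped_map(path, panel, age_window)
    raise ValidationError(f"unknown format {format!r}")


def _resolve_panel(
    rs_ids: Sequence[str],
    declared: Mapping[str, SnpDef],
    panel: Sequence[SnpDef] | None,
    raw_columns: Mapping[str, list[str]],
) -> tuple[SnpDef, ...]:
    by_rs = {s.rs_id: s for s in (panel or DEFAULT_PANEL)}
    out = []
    for rs in rs_ids:
        if rs in declared:
            out.append(declared[rs])
        elif rs in by_rs:
            out.append(by_rs[rs])
        else:
            alleles = sorted(
                {a for g in raw_columns[rs] for a in g if g not in _MISSING_GT}
            )
            if len(alleles) != 2:
                raise ValidationError(
                    f"{rs}: cannot infer a biallelic definition "
                    f"(saw alleles {alleles})"
                )
            out.append(SnpDef(rs, rs, alleles[0], alleles[1], None))
    return tuple(out)


def _read_tsv(
    path: Path, panel: Sequence[SnpDef] | None, age_window: tuple[int, int] | None
) -> CohortDataset:
    declared: dict[str, SnpDef] = {}
    file_window: tuple[int, int] | None = None
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#snp\t"):
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError("malformed #snp metadata line", line=line_no)
            _, rs, gene, a, b, risk = parts
            declared[rs] = SnpDef(rs, gene, a, b, None if risk == "unset" else risk)
            continue
        if line.startswith("#age_window\t"):
            _, lo, hi = line.split("\t")
            file_window = (int(lo), int(hi))
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if tuple(header[:7]) != PHENOTYPE_COLUMNS:
                raise ParseError(
                    f"header must start with {' '.join(PHENOTYPE_COLUMNS)}",
                    line=line_no,
                )
            continue
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(fields)}", line=line_no
            )
        rows.append((line_no, fields))
    if header is None:
        raise ParseError(f"{path}: no header line found")
    rs_ids = header[7:]
    raw_cols = {rs: [fields[7 + j] for _, fields in rows] for j, rs in enumerate(rs_ids)}
    snps = _resolve_panel(rs_ids, declared, panel, raw_cols)
    subjects, genotypes = [], []
    for line_no, fields in rows:
        subj = _subject_from_fields(fields, line_no)
        subjects.append(subj)
        genotypes.append(
            [
                _normalize_genotype(fields[7 + j], snp, subj.id)
                for j, snp in enumerate(snps)
            ]
        )
    window = age_window or file_window or (0, 49)
    return CohortDataset(snps, subjects, np.array(genotypes, dtype=object), window)


def _read_ped_map(
    ped_path: Path, panel: Sequence[SnpDef] | None, age_window: tuple[int, int] | None
) -> CohortDataset:
    """PLINK-style reader: ped columns famid id pat mat sex(1/2) pheno(1/2),
    then two allele columns per SNP; map columns chrom rs cM bp.  A side-car
    ``<stem>.pheno.tsv`` (id hereditary location lauren age) supplies the
    phenotype detail the ped format cannot carry."""
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise ParseError(f"no such file: {map_path}")
    rs_ids = []
    for line_no, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError("map line must have 4 columns", line=line_no)
        rs_ids.append(parts[1])

    sidecar: dict[str, dict[str, str]] = {}
    sidecar_path = ped_path.with_suffix(".pheno.tsv")
    if sidecar_path.exists():
        lines = sidecar_path.read_text().splitlines()
        cols = lines[0].split("\t")
        for line in lines[1:]:
            if not line.strip():
                continue
            rec = dict(zip(cols, line.split("\t")))
            sidecar[rec["id"]] = rec

    raw_rows = []
    for line_no, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(rs_ids):
            raise ParseError(
                f"ped line must have {6 + 2 * len(rs_ids)} columns, "
                f"got {len(parts)}",
                line=line_no,
            )
        raw_rows.append((line_no, parts))

    raw_cols = {
        rs: [parts[6 + 2 * j] + parts[7 + 2 * j] for _, parts in raw_rows]
        for j, rs in enumerate(rs_ids)
    }
    snps = _resolve_panel(rs_ids, {}, panel, raw_cols)

    subjects, genotypes = [], []
    for line_no, parts in raw_rows:
        sid = parts[1]
        sex = {"1": "M", "2": "F"}.get(parts[4])
        if sex is None:
            raise ParseError(f"subject {sid}: bad ped sex code {parts[4]!r}", line=line_no)
        status = {"1": "control", "2": "case"}.get(parts[5])
        if status is None:
            raise ParseError(
                f"subject {sid}: bad ped phenotype code {parts[5]!r}", line=line_no
            )
        extra = sidecar.get(sid, {})
        hered = _HERED_IN.get(extra.get("hereditary", "NA"), "na")
        if status == "case" and hered == "na":
            hered = "no"
        if status == "control":
            hered = "na"
        subj = Subject(
            sid,
            status,
            sex,
            int(extra.get("age", 0)),
            hered,
            extra.get("location", "unknown") if status == "case" else "unknown",
            extra.get("lauren", "unknown") if status == "case" else "unknown",
        )
        subjects.append(subj)
        row = []
        for j, snp in enumerate(snps):
            raw = parts[6 + 2 * j] + parts[7 + 2 * j]
            row.append(
                None if raw in _MISSING_GT else _normalize_genotype(raw, snp, sid)
            )
        genotypes.append(row)
    window = age_window or (0, 49)
    return CohortDataset(snps, subjects, np.array(genotypes, dtype=object), window)
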
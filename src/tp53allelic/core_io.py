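"""Domain types and tabular I/O shared by every analysis stage.

Variant allele frequencies (VAFs) are stored internally as *fractions* in
[0, 1].  All file interfaces speak *percent* (0-100), which is how clinical
sequencing reports print them; conversion happens at the I/O boundary and
nowhere else.

The cohort is held in three normalized long-format tables because a patient
carries 0..n TP53 variants:

* ``patients.tsv`` — patient_id, subtype, os_months, os_event (0/1)
* ``variants.tsv`` — patient_id, effect, protein_change, vaf_percent
* ``cyto.tsv``     — patient_id, del17p (0/1), del17p_clonality_percent
  (blank when the deleted-cell fraction was not quantified), upd17p (0/1),
  complex_karyotype (0/1)

A patient absent from ``cyto.tsv`` simply has no cytogenetic record; that is
distinct from ``del17p=0`` (tested, not found) and from a present deletion
whose clonality is unknown (``del17p=1`` with a blank clonality field).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

logger = logging.getLogger("tp53allelic")

PathLike = Union[str, Path]

__all__ = [
    "Effect",
    "Subtype",
    "TraditionalLabel",
    "AllelicLabel",
    "Rule",
    "VariantCall",
    "CytoRecord",
    "PatientRecord",
    "AllelicCall",
    "RunConfig",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "write_calls",
    "read_calls",
    "load_config",
]


class CohortError(ValueError):
    """Raised when cohort tables violate the documented contract."""


class Effect(str, enum.Enum):
    """Coding consequence of a TP53 variant."""

    missense = "missense"
    truncated = "truncated"
    other = "other"


class Subtype(str, enum.Enum):
    """Myeloid-neoplasm disease subtype."""

    pAML = "pAML"
    sAML = "sAML"
    HR_MDS = "HR_MDS"
    LR_MDS = "LR_MDS"
    MDS_MPN = "MDS_MPN"
    other = "other"


class TraditionalLabel(str, enum.Enum):
    """Lesion-counting classification: single vs double TP53 hit."""

    WT = "WT"
    single_hit = "single_hit"
    double_hit = "double_hit"


class AllelicLabel(str, enum.Enum):
    """Three-class allelic-configuration call (plus WT / deletion-only)."""

    WT = "WT"
    obligatory_biallelic = "obligatory_biallelic"
    probable_biallelic = "probable_biallelic"
    probable_monoallelic = "probable_monoallelic"
    del17p_only = "del17p_only"


class Rule(str, enum.Enum):
    """Which classification rule produced an :class:`AllelicCall`."""

    none = "none"
    single_vaf_gt50 = "single_vaf_gt50"
    combined_vaf_gt50 = "combined_vaf_gt50"
    vaf_plus_del17p_gt50 = "vaf_plus_del17p_gt50"
    cutoff_above = "cutoff_above"
    cutoff_at_or_below = "cutoff_at_or_below"


#: Rules that imply an obligatory biallelic configuration.
OBLIGATORY_RULES = frozenset(
    {Rule.single_vaf_gt50, Rule.combined_vaf_gt50, Rule.vaf_plus_del17p_gt50}
)


@dataclass(frozen=True)
class VariantCall:
    """A single TP53 variant in one patient.

    ``vaf`` is the variant allele frequency as a fraction of reads in
    [0, 1]; ``protein_change`` is a free-text HGVS-style label such as
    ``"R175H"`` and is carried, never interpreted.
    """

    patient_id: str
    effect: Effect
    vaf: float
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise CohortError(
                f"VAF must lie in [0, 1], got {self.vaf!r} for patient "
                f"{self.patient_id!r}"
            )
        if not isinstance(self.effect, Effect):
            object.__setattr__(self, "effect", Effect(self.effect))


@dataclass(frozen=True)
class CytoRecord:
    """Cytogenetic findings at the TP53 locus for one patient.

    ``del17p_clonality`` is the fraction of cells carrying the 17p deletion
    when the assay quantified it; ``None`` means the deletion was seen but
    its clonality is unknown — a state the classifier must handle explicitly
    rather than treating as zero.
    """

    patient_id: str
    del17p: bool = False
    del17p_clonality: Optional[float] = None
    upd17p: bool = False
    complex_karyotype: bool = False

    def __post_init__(self) -> None:
        if self.del17p_clonality is not None:
            if not self.del17p:
                raise CohortError(
                    f"del17p clonality given without del17p for patient "
                    f"{self.patient_id!r}"
                )
            if not (0.0 <= self.del17p_clonality <= 1.0):
                raise CohortError(
                    f"del17p clonality must lie in [0, 1], got "
                    f"{self.del17p_clonality!r} for patient {self.patient_id!r}"
                )


@dataclass(frozen=True)
class PatientRecord:
    """One subject: outcome, disease subtype, TP53 variants, cytogenetics.

    ``os_months`` is overall survival in months from diagnosis;
    ``os_event`` is True when death was observed (False = censored).
    An empty ``variants`` list means TP53 wild type by sequencing.
    """

    patient_id: str
    subtype: Subtype
    os_months: float
    os_event: bool
    variants: tuple[VariantCall, ...] = ()
    cyto: Optional[CytoRecord] = None

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise CohortError(
                f"os_months must be non-negative, got {self.os_months!r} "
                f"for patient {self.patient_id!r}"
            )
        if not isinstance(self.variants, tuple):
            object.__setattr__(self, "variants", tuple(self.variants))

    @property
    def has_mutation(self) -> bool:
        return len(self.variants) > 0

    @property
    def has_del17p(self) -> bool:
        return self.cyto is not None and self.cyto.del17p

    @property
    def has_upd17p(self) -> bool:
        return self.cyto is not None and self.cyto.upd17p


@dataclass(frozen=True)
class AllelicCall:
    """Result of the allelic-configuration classification for one patient."""

    patient_id: str
    label: AllelicLabel
    rule_fired: Rule
    combined_vaf: float
    evidence_note: str = ""

    def __post_init__(self) -> None:
        obligatory = self.label is AllelicLabel.obligatory_biallelic
        if obligatory != (self.rule_fired in OBLIGATORY_RULES):
            raise CohortError(
                f"inconsistent call for {self.patient_id!r}: label "
                f"{self.label.value} with rule {self.rule_fired.value}"
            )
        probable = self.label in (
            AllelicLabel.probable_biallelic,
            AllelicLabel.probable_monoallelic,
        )
        cutoff_rule = self.rule_fired in (Rule.cutoff_above, Rule.cutoff_at_or_below)
        if probable != cutoff_rule:
            raise CohortError(
                f"inconsistent call for {self.patient_id!r}: label "
                f"{self.label.value} with rule {self.rule_fired.value}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; every stochastic stage draws from ``seed``.

    cutoff
        VAF fraction separating probable monoallelic from probable
        biallelic calls among patients without obligatory evidence.
    min_node
        Minimum number of patients on each side of a candidate split.
    cv_runs / test_fraction
        Number of random train/test splits and the test-set share used by
        the cross-validated cutoff search.
    subsamples
        Bootstrap resamples for the split-stability profile.
    del17p_detection_limit
        Smallest deleted-cell fraction the cytogenetic assay can see.
    """

    cutoff: float = 0.23
    min_node: int = 15
    cv_runs: int = 30
    test_fraction: float = 0.2
    subsamples: int = 1000
    seed: int = 0
    del17p_detection_limit: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 0.5):
            raise CohortError(f"cutoff must lie in (0, 0.5), got {self.cutoff!r}")
        if self.min_node < 2:
            raise CohortError(f"min_node must be >= 2, got {self.min_node!r}")
        if not (0.0 < self.test_fraction < 1.0):
            raise CohortError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction!r}"
            )
        if self.cv_runs < 1 or self.subsamples < 1:
            raise CohortError("cv_runs and subsamples must be positive")

    def with_cutoff(self, cutoff: float) -> "RunConfig":
        return replace(self, cutoff=cutoff)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PATIENT_COLUMNS = ["patient_id", "subtype", "os_months", "os_event"]
_VARIANT_COLUMNS = ["patient_id", "effect", "protein_change", "vaf_percent"]
_CYTO_COLUMNS = [
    "patient_id",
    "del17p",
    "del17p_clonality_percent",
    "upd17p",
    "complex_karyotype",
]
_CALL_COLUMNS = [
    "patient_id",
    "label",
    "rule_fired",
    "combined_vaf_percent",
    "evidence_note",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing column(s) {missing}")


def read_cohort(
    patients_path: PathLike,
    variants_path: Optional[PathLike] = None,
    cyto_path: Optional[PathLike] = None,
) -> list[PatientRecord]:
    """Load and join the three cohort tables into :class:`PatientRecord` s.

    VAFs and clonalities are given in percent on file and converted to
    fractions here.  Referential integrity is enforced: a variant or
    cytogenetic row for a patient missing from the patients table is a hard
    error, as is a duplicate patient_id or a VAF outside [0, 100].  An
    unrecognised subtype string is kept as :attr:`Subtype.other` with a
    logged warning.  Records are returned in patients-table order.
    """
    pat = pd.read_csv(patients_path, sep="\t", dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(pat, _PATIENT_COLUMNS, patients_path)

    dups = pat["patient_id"][pat["patient_id"].duplicated()].tolist()
    if dups:
        raise CohortError(f"{patients_path}: duplicate patient_id(s) {sorted(set(dups))}")
    known_ids = set(pat["patient_id"])

    variants: dict[str, list[VariantCall]] = {pid: [] for pid in known_ids}
    if variants_path is not None:
        var = pd.read_csv(variants_path, sep="\t", dtype={"patient_id": str}, float_precision="round_trip")
        _require_columns(var, _VARIANT_COLUMNS, variants_path)
        orphans = sorted(set(var["patient_id"]) - known_ids)
        if orphans:
            raise CohortError(
                f"{variants_path}: variant rows for patient(s) absent from the "
                f"patients table: {orphans}"
            )
        for idx, row in var.iterrows():
            vaf_pct = float(row["vaf_percent"])
            if not (0.0 <= vaf_pct <= 100.0) or math.isnan(vaf_pct):
                raise CohortError(
                    f"{variants_path} row {idx}: vaf_percent {vaf_pct!r} outside "
                    f"[0, 100] (patient {row['patient_id']!r})"
                )
            protein = row.get("protein_change")
            if pd.isna(protein) or protein == "":
                protein = None
            variants[row["patient_id"]].append(
                VariantCall(
                    patient_id=row["patient_id"],
                    effect=Effect(row["effect"]),
                    vaf=vaf_pct / 100.0,
                    protein_change=protein,
                )
            )

    cyto: dict[str, CytoRecord] = {}
    if cyto_path is not None:
        cy = pd.read_csv(cyto_path, sep="\t", dtype={"patient_id": str}, float_precision="round_trip")
        _require_columns(cy, _CYTO_COLUMNS, cyto_path)
        orphans = sorted(set(cy["patient_id"]) - known_ids)
        if orphans:
            raise CohortError(
                f"{cyto_path}: cytogenetic rows for patient(s) absent from the "
                f"patients table: {orphans}"
            )
        cy_dups = cy["patient_id"][cy["patient_id"].duplicated()].tolist()
        if cy_dups:
            raise CohortError(f"{cyto_path}: duplicate patient_id(s) {sorted(set(cy_dups))}")
        for idx, row in cy.iterrows():
            clon = row["del17p_clonality_percent"]
            clon_frac: Optional[float]
            if pd.isna(clon) or clon == "":
                clon_frac = None
            else:
                clon_frac = float(clon) / 100.0
                if not (0.0 <= clon_frac <= 1.0):
                    raise CohortError(
                        f"{cyto_path} row {idx}: del17p_clonality_percent "
                        f"{clon!r} outside [0, 100]"
                    )
            cyto[row["patient_id"]] = CytoRecord(
                patient_id=row["patient_id"],
                del17p=bool(int(row["del17p"])),
                del17p_clonality=clon_frac,
                upd17p=bool(int(row["upd17p"])),
                complex_karyotype=bool(int(row["complex_karyotype"])),
            )

    records: list[PatientRecord] = []
    for _, row in pat.iterrows():
        raw_subtype = str(row["subtype"])
        try:
            subtype = Subtype(raw_subtype)
        except ValueError:
            logger.warning(
                "patient %s: unknown subtype %r kept as 'other'",
                row["patient_id"],
                raw_subtype,
            )
            subtype = Subtype.other
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                subtype=subtype,
                os_months=float(row["os_months"]),
                os_event=bool(int(row["os_event"])),
                variants=tuple(variants[row["patient_id"]]),
                cyto=cyto.get(row["patient_id"]),
            )
        )
    return records


def write_cohort(
    cohort: Sequence[PatientRecord],
    patients_path: PathLike,
    variants_path: PathLike,
    cyto_path: PathLike,
) -> None:
    """Write a cohort back to the three-table TSV layout (percent units)."""
    pat_rows = []
    var_rows = []
    cyto_rows = []
    for p in cohort:
        pat_rows.append(
            {
                "patient_id": p.patient_id,
                "subtype": p.subtype.value,
                "os_months": repr(p.os_months),
                "os_event": int(p.os_event),
            }
        )
        for v in p.variants:
            var_rows.append(
                {
                    "patient_id": v.patient_id,
                    "effect": v.effect.value,
                    "protein_change": v.protein_change or "",
                    "vaf_percent": repr(v.vaf * 100.0),
                }
            )
        if p.cyto is not None:
            c = p.cyto
            cyto_rows.append(
                {
                    "patient_id": c.patient_id,
                    "del17p": int(c.del17p),
                    "del17p_clonality_percent": (
                        "" if c.del17p_clonality is None else repr(c.del17p_clonality * 100.0)
                    ),
                    "upd17p": int(c.upd17p),
                    "complex_karyotype": int(c.complex_karyotype),
                }
            )
    pd.DataFrame(pat_rows, columns=_PATIENT_COLUMNS).to_csv(
        patients_path, sep="\t", index=False
    )
    pd.DataFrame(var_rows, columns=_VARIANT_COLUMNS).to_csv(
        variants_path, sep="\t", index=False
    )
    pd.DataFrame(cyto_rows, columns=_CYTO_COLUMNS).to_csv(cyto_path, sep="\t", index=False)


def write_calls(
    cohort: Sequence[PatientRecord],
    calls: Sequence[AllelicCall],
    path: PathLike,
) -> None:
    """Write one classification row per patient, in cohort order.

    Calls may arrive in any order; they are keyed by patient_id.  A missing
    or surplus call is a hard error.
    """
    by_id = {c.patient_id: c for c in calls}
    if len(by_id) != len(calls):
        raise CohortError("duplicate patient_id among calls")
    cohort_ids = [p.patient_id for p in cohort]
    missing = [pid for pid in cohort_ids if pid not in by_id]
    surplus = sorted(set(by_id) - set(cohort_ids))
    if missing or surplus:
        raise CohortError(
            f"calls do not match cohort (missing {missing[:5]}, surplus {surplus[:5]})"
        )
    rows = []
    for pid in cohort_ids:
        c = by_id[pid]
        rows.append(
            {
                "patient_id": c.patient_id,
                "label": c.label.value,
                "rule_fired": c.rule_fired.value,
                "combined_vaf_percent": repr(c.combined_vaf * 100.0),
                "evidence_note": c.evidence_note,
            }
        )
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: PathLike) -> list[AllelicCall]:
    """Read back a calls table written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str}, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, _CALL_COLUMNS, path)
    return [
        AllelicCall(
            patient_id=row["patient_id"],
            label=AllelicLabel(row["label"]),
            rule_fired=Rule(row["rule_fired"]),
            combined_vaf=float(row["combined_vaf_percent"]) / 100.0,
            evidence_note=str(row["evidence_note"]),
        )
        for _, row in df.iterrows()
    ]


def load_config(path: PathLike) -> RunConfig:
    """Parse a flat ``key: value`` configuration file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise CohortError(f"{path}: expected flat key: value pairs")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise CohortError(f"{path}: unknown config key(s) {unknown}")
    return RunConfig(**raw)
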
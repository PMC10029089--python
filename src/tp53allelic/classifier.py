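"""TP53 hit classification: traditional lesion counting and the
VAF-arithmetic allelic-configuration scheme.

The traditional scheme counts lesions without asking whether they co-occur
in the same cell: one mutation or an isolated 17p deletion is a *single
hit*; a mutation plus any second lesion (another mutation, del17p, or 17p
UPD) is a *double hit*.

The allelic scheme instead asks what the VAF arithmetic forces.  In diploid
cells a fully clonal heterozygous mutation sits at VAF 50%, so

* a single mutation with VAF > 50%,
* two mutations (assumed in trans) with combined VAF > 50%, or
* a mutation whose VAF plus the del17p clonality exceeds 50%

cannot be explained without cells carrying two inactivated alleles: the
configuration is *obligatory biallelic*.  Below that bound the bulk signal
cannot distinguish subclonal mosaicism from a biallelic clone, and the
remaining mutated patients are split at a survival-calibrated VAF cutoff
(default 23%) into *probable biallelic* (above) and *probable monoallelic*
(at or below).  All inequalities are strict: a combined VAF of exactly 50%
is not obligatory, and a VAF exactly at the cutoff is probable monoallelic.

Uniparental disomy does not promote a call by itself: homozygosity through
UPD doubles the mutation's VAF, so the VAF rules already contain that
evidence.  Patients with a 17p deletion but no mutation fall outside the
mutation classes and receive the separate ``del17p_only`` label.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .core_io import (
    AllelicCall,
    AllelicLabel,
    PatientRecord,
    Rule,
    RunConfig,
    TraditionalLabel,
    VariantCall,
)

logger = logging.getLogger("tp53allelic")

__all__ = [
    "combined_vaf",
    "classify_traditional",
    "classify_allelic",
    "classify_cohort",
    "reclassification_table",
    "ORDINAL_RISK",
    "ordinal_risk_score",
]


def combined_vaf(variants: Iterable[VariantCall]) -> float:
    """Sum of the per-variant VAF fractions, capped at 1.0.

    All mutations in a patient are summed (three or more co-occurring
    mutations do happen); an empty list sums to 0.  A raw sum above 1 is
    arithmetically impossible for real reads and is capped with a warning —
    it can arise from sampling noise at very high VAFs.
    """
    total = sum(v.vaf for v in variants)
    if total > 1.0:
        logger.warning("combined VAF %.4f exceeds 1.0; capping", total)
        total = 1.0
    return total


def classify_traditional(patient: PatientRecord) -> TraditionalLabel:
    """Single/double-hit call by lesion counting.

    WT: no mutation and no del17p.  Single hit: exactly one mutation with
    no del17p/UPD, or an isolated del17p without mutation.  Double hit: two
    or more mutations, or at least one mutation together with del17p or
    17p UPD.  UPD without any mutation does not count as a hit.
    """
    n = len(patient.variants)
    if n == 0:
        return TraditionalLabel.single_hit if patient.has_del17p else TraditionalLabel.WT
    if n >= 2 or patient.has_del17p or patient.has_upd17p:
        return TraditionalLabel.double_hit
    return TraditionalLabel.single_hit


def classify_allelic(patient: PatientRecord, config: RunConfig) -> AllelicCall:
    """Assign the allelic-configuration label by the first matching rule.

    Rule order (first match wins):

    0.  no mutation, no del17p            -> WT
    0b. no mutation, del17p present       -> del17p_only
    1.  any single variant VAF > 0.50     -> obligatory_biallelic
    2.  combined VAF > 0.50               -> obligatory_biallelic
    3.  del17p with known clonality and
        combined VAF + clonality > 0.50   -> obligatory_biallelic
    4.  combined VAF > cutoff             -> probable_biallelic
    5.  otherwise                         -> probable_monoallelic

    A del17p whose clonality was not quantified skips rule 3 (nothing is
    imputed) and the call is flagged ``clonality_unknown`` in the evidence
    note.
    """
    cv = combined_vaf(patient.variants)
    pid = patient.patient_id
    cyto = patient.cyto
    notes: list[str] = []

    if not patient.variants:
        if patient.has_del17p:
            return AllelicCall(pid, AllelicLabel.del17p_only, Rule.none, 0.0, "del17p without TP53 mutation")
        return AllelicCall(pid, AllelicLabel.WT, Rule.none, 0.0, "no TP53 lesion")

    if any(v.vaf > 0.5 for v in patient.variants):
        top = max(v.vaf for v in patient.variants)
        return AllelicCall(
            pid,
            AllelicLabel.obligatory_biallelic,
            Rule.single_vaf_gt50,
            cv,
            f"single-variant VAF {top:.3f} > 0.50",
        )
    if cv > 0.5:
        return AllelicCall(
            pid,
            AllelicLabel.obligatory_biallelic,
            Rule.combined_vaf_gt50,
            cv,
            f"combined VAF {cv:.3f} > 0.50",
        )
    if patient.has_del17p:
        assert cyto is not None
        if cyto.del17p_clonality is not None:
            if cv + cyto.del17p_clonality > 0.5:
                return AllelicCall(
                    pid,
                    AllelicLabel.obligatory_biallelic,
                    Rule.vaf_plus_del17p_gt50,
                    cv,
                    f"combined VAF {cv:.3f} + del17p clonality "
                    f"{cyto.del17p_clonality:.3f} > 0.50",
                )
        else:
            notes.append("clonality_unknown")

    if cv > config.cutoff:
        notes.insert(0, f"combined VAF {cv:.3f} > cutoff {config.cutoff:.3f}")
        return AllelicCall(pid, AllelicLabel.probable_biallelic, Rule.cutoff_above, cv, "; ".join(notes))
    notes.insert(0, f"combined VAF {cv:.3f} <= cutoff {config.cutoff:.3f}")
    return AllelicCall(pid, AllelicLabel.probable_monoallelic, Rule.cutoff_at_or_below, cv, "; ".join(notes))


def classify_cohort(
    cohort: Sequence[PatientRecord], config: RunConfig
) -> list[AllelicCall]:
    """Vector convenience: one :func:`classify_allelic` call per patient."""
    return [classify_allelic(p, config) for p in cohort]


_TRAD_ORDER = [TraditionalLabel.WT, TraditionalLabel.single_hit, TraditionalLabel.double_hit]
_ALLELIC_ORDER = [
    AllelicLabel.WT,
    AllelicLabel.del17p_only,
    AllelicLabel.probable_monoallelic,
    AllelicLabel.probable_biallelic,
    AllelicLabel.obligatory_biallelic,
]


def reclassification_table(
    cohort: Sequence[PatientRecord], config: RunConfig
) -> pd.DataFrame:
    """Cross-tabulate traditional hit class against the allelic call.

    Rows are traditional labels, columns allelic labels; cell counts sum to
    the cohort size.  The off-diagonal mass is the point of the exercise:
    single hits re-classified as probable biallelic, and double hits whose
    combined VAF cannot support a biallelic clone.
    """
    table = pd.DataFrame(
        0,
        index=pd.Index([t.value for t in _TRAD_ORDER], name="traditional"),
        columns=pd.Index([a.value for a in _ALLELIC_ORDER], name="allelic"),
        dtype=int,
    )
    for p in cohort:
        trad = classify_traditional(p)
        allelic = classify_allelic(p, config)
        table.loc[trad.value, allelic.label.value] += 1
    return table


#: Ordinal risk encoding used wherever the classes enter a concordance
#: computation.  Monotone in expected hazard; deletion-only cases group
#: with WT because the mutation classes do not apply to them.
ORDINAL_RISK: dict[AllelicLabel, int] = {
    AllelicLabel.WT: 0,
    AllelicLabel.del17p_only: 0,
    AllelicLabel.probable_monoallelic: 1,
    AllelicLabel.probable_biallelic: 2,
    AllelicLabel.obligatory_biallelic: 3,
}


def ordinal_risk_score(patient: PatientRecord, config: RunConfig) -> int:
    """Risk score of a patient's allelic call under ``config.cutoff``."""
    return ORDINAL_RISK[classify_allelic(patient, config).label]
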
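"""Ground-truthed cohort simulator: clonal architectures, bulk VAFs,
cytogenetic calls with a detection floor, survival, and single-cell draws.

A patient's marrow is modelled as a mixture of cell states.  Each state
carries a TP53 copy number at the locus (1 in cells with del17p, 2
otherwise), a per-mutation count of mutant copies, and its fraction of the
cell population.  From that architecture everything observable follows:

* the expected bulk VAF of mutation m is the copy-weighted ratio
  sum_i f_i * mut_im / sum_i f_i * copies_i;
* sequencing draws binomial reads around that expectation at a
  Poisson-distributed depth;
* the cytogenetic assay reports del17p only when the deleted-cell fraction
  reaches its detection floor (default 20%), so small deleted clones are
  *cryptic*;
* survival is exponential with a stratum-specific median — wild type,
  monoallelic, or biallelic-containing — where a patient is in the
  biallelic stratum as soon as the true fraction of cells with two
  inactivated alleles exceeds a small threshold (default 2%): presence of
  the biallelic clone, not its size, drives the hazard;
* single-cell genotyping samples cells multinomially and hides each allele
  observation independently with the allelic-dropout probability.

A cell has two inactivated alleles when its mutant copies plus its lost
copies reach two: compound heterozygous (two mutations in trans),
homozygous via UPD, or hemizygous (one mutation on the sole copy retained
after deletion).  The central discordance the simulator must reproduce is
the *cryptic biallelic* case: a small biallelic subclone whose bulk
combined VAF stays below the classification cutoff, so bulk sequencing
calls the patient probable monoallelic while the survival hazard is
already biallelic-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_io import (
    CytoRecord,
    Effect,
    PatientRecord,
    Subtype,
    VariantCall,
)

__all__ = [
    "CellState",
    "ClonalArchitecture",
    "SimParams",
    "SingleCellDraw",
    "expected_vaf",
    "sample_bulk_vaf",
    "call_del17p",
    "sample_survival",
    "sample_single_cells",
    "simulate_cohort",
    "simulate_changepoint_cohort",
    "arch_wild_type",
    "arch_heterozygous",
    "arch_upd_homozygous",
    "arch_cryptic_biallelic",
    "arch_compound_heterozygous",
    "arch_del17p_hemizygous",
    "arch_mosaic_two_clones",
]

#: truth strata used for hazard assignment and reporting
STRATUM_WT = "WT"
STRATUM_MONO = "monoallelic"
STRATUM_BIALLELIC = "biallelic"


@dataclass(frozen=True)
class CellState:
    """A clone: locus copy number, mutant copies per mutation, and size.

    ``mutant_copies`` has one entry per mutation tracked in the patient;
    each entry is bounded by ``total_copies``.
    """

    total_copies: int
    mutant_copies: tuple[int, ...]
    fraction: float

    def __post_init__(self) -> None:
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if any(m < 0 or m > self.total_copies for m in self.mutant_copies):
            raise ValueError("mutant copies must lie in [0, total_copies]")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("state fraction must lie in [0, 1]")

    @property
    def inactivated_alleles(self) -> int:
        """Mutant copies plus copies lost relative to the diploid two."""
        return sum(self.mutant_copies) + max(0, 2 - self.total_copies)

    @property
    def is_biallelic(self) -> bool:
        return self.inactivated_alleles >= 2

    @property
    def is_deleted(self) -> bool:
        return self.total_copies < 2


@dataclass(frozen=True)
class ClonalArchitecture:
    """Cell-state mixture with its derived ground truth."""

    states: tuple[CellState, ...]
    n_mutations: int
    truth_biallelic_fraction: float

    def __post_init__(self) -> None:
        total = sum(s.fraction for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, not 1")
        if any(len(s.mutant_copies) != self.n_mutations for s in self.states):
            raise ValueError("every state must list one mutant count per mutation")
        recomputed = compute_biallelic_fraction(self.states)
        if abs(recomputed - self.truth_biallelic_fraction) > 1e-9:
            raise ValueError(
                f"stored biallelic fraction {self.truth_biallelic_fraction} "
                f"disagrees with states ({recomputed})"
            )

    @classmethod
    def from_states(cls, states: Sequence[CellState], n_mutations: int) -> "ClonalArchitecture":
        states = tuple(states)
        return cls(
            states=states,
            n_mutations=n_mutations,
            truth_biallelic_fraction=compute_biallelic_fraction(states),
        )

    @property
    def deleted_fraction(self) -> float:
        return sum(s.fraction for s in self.states if s.is_deleted)

    @property
    def upd_fraction(self) -> float:
        """Cells homozygous-mutant at normal copy number (CN-LOH)."""
        return sum(
            s.fraction
            for s in self.states
            if s.total_copies == 2 and any(m == 2 for m in s.mutant_copies)
        )


def compute_biallelic_fraction(states: Sequence[CellState]) -> float:
    return sum(s.fraction for s in states if s.is_biallelic)


# ---------------------------------------------------------------------------
# architecture builders
# ---------------------------------------------------------------------------

def _with_wt_rest(states: list[CellState], n_mutations: int) -> ClonalArchitecture:
    used = sum(s.fraction for s in states)
    if used > 1.0 + 1e-9:
        raise ValueError(f"clone fractions sum to {used} > 1")
    rest = max(0.0, 1.0 - used)
    if rest > 1e-12:
        states = states + [CellState(2, (0,) * n_mutations, rest)]
    return ClonalArchitecture.from_states(states, n_mutations)


def arch_wild_type() -> ClonalArchitecture:
    return ClonalArchitecture.from_states([CellState(2, (), 1.0)], 0)


def arch_heterozygous(clone_fraction: float) -> ClonalArchitecture:
    """One heterozygous mutant clone; bulk VAF = clone_fraction / 2."""
    return _with_wt_rest([CellState(2, (1,), clone_fraction)], 1)


def arch_upd_homozygous(clone_fraction: float) -> ClonalArchitecture:
    """Homozygous-mutant clone via CN-LOH; bulk VAF = clone_fraction."""
    return _with_wt_rest([CellState(2, (2,), clone_fraction)], 1)


def arch_cryptic_biallelic(
    biallelic_fraction: float, het_fraction: float
) -> ClonalArchitecture:
    """Small UPD-homozygous subclone inside a heterozygous clone.

    Branching evolution of one mutation: ``biallelic_fraction`` of cells
    became homozygous through CN-LOH while ``het_fraction`` remain
    heterozygous.  Bulk VAF = biallelic_fraction + het_fraction / 2, which
    stays below any useful cutoff when both clones are small — the
    configuration bulk sequencing cannot see.
    """
    return _with_wt_rest(
        [
            CellState(2, (2,), biallelic_fraction),
            CellState(2, (1,), het_fraction),
        ],
        1,
    )


def arch_compound_heterozygous(clone_fraction: float) -> ClonalArchitecture:
    """One clone carrying two different mutations in trans."""
    return _with_wt_rest([CellState(2, (1, 1), clone_fraction)], 2)


def arch_del17p_hemizygous(deleted_fraction: float) -> ClonalArchitecture:
    """Deletion clone mutated on the retained copy (hemizygous mutant).

    Bulk VAF = f / (2 - f) for deleted-cell fraction f; the deletion's
    clonality equals f.
    """
    return _with_wt_rest([CellState(1, (1,), deleted_fraction)], 1)


def arch_mosaic_two_clones(f1: float, f2: float) -> ClonalArchitecture:
    """Two independent monoallelic clones, one mutation each (mosaicism).

    No cell carries two hits, so the truth is monoallelic even though the
    patient shows two mutations — the double-hit-but-not-biallelic case.
    """
    return _with_wt_rest(
        [
            CellState(2, (1, 0), f1),
            CellState(2, (0, 1), f2),
        ],
        2,
    )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _default_class_mix() -> dict[str, float]:
    # Mutated-architecture ratios follow the reported class shares
    # (obligatory 57 / probable biallelic 24 / probable monoallelic 19 among
    # mutated patients), with the obligatory share split between pure-mutation
    # and deletion-involving configurations in line with the ~17% del17p rate
    # among mutated patients.  The wild-type share is held at 30% so that a
    # desk-scale cohort retains usable per-class counts.
    mutated = 0.70
    return {
        "WT": 0.30,
        "monoallelic": round(0.19 * mutated, 6),
        "cryptic_biallelic": round(0.24 * mutated, 6),
        "dominant_biallelic": round(0.40 * mutated, 6),
        "del17p_involving": round(0.17 * mutated, 6),
    }


def _default_medians() -> dict[str, float]:
    return {STRATUM_WT: 42.0, STRATUM_MONO: 29.0, STRATUM_BIALLELIC: 14.0}


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions.

    class_mix
        Proportions over architecture families {WT, monoallelic,
        cryptic_biallelic, dominant_biallelic, del17p_involving}.
    depth
        Mean sequencing depth; per-variant depth is Poisson around it.
    hazard_medians
        Median overall survival (months) per truth stratum.
    biallelic_hazard_threshold
        Smallest true biallelic cell fraction that places a patient in the
        biallelic hazard stratum; presence, not size, drives the hazard.
    censor_rate
        Fraction of subjects whose follow-up ends (uniformly) before the
        event.
    ado_rate
        Per-allele dropout probability in single-cell genotyping.
    """

    n_patients: int = 1000
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    depth: float = 500.0
    del17p_detection_limit: float = 0.20
    hazard_medians: dict[str, float] = field(default_factory=_default_medians)
    biallelic_hazard_threshold: float = 0.02
    censor_rate: float = 0.2
    ado_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mix sums to {total}, not 1")
        if any(m <= 0 for m in self.hazard_medians.values()):
            raise ValueError("hazard medians must be positive")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def expected_vaf(arch: ClonalArchitecture, mutation_index: int) -> float:
    """Copy-weighted expected bulk VAF of one mutation."""
    if not (0 <= mutation_index < arch.n_mutations):
        raise IndexError(f"mutation index {mutation_index} out of range")
    num = sum(s.fraction * s.mutant_copies[mutation_index] for s in arch.states)
    den = sum(s.fraction * s.total_copies for s in arch.states)
    if den == 0:
        raise ValueError("architecture has no TP53 copies at all")
    return num / den


def sample_bulk_vaf(
    arch: ClonalArchitecture,
    mutation_index: int,
    depth: float,
    rng: np.random.Generator,
) -> float:
    """Observed VAF: binomial reads at Poisson depth around the mean."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    d = max(1, int(rng.poisson(depth)))
    p = expected_vaf(arch, mutation_index)
    return rng.binomial(d, p) / d


def call_del17p(
    arch: ClonalArchitecture,
    detection_limit: float,
    rng: np.random.Generator,
    clonality_noise_sd: float = 0.02,
) -> tuple[bool, Optional[float]]:
    """Cytogenetic deletion call with a detection floor.

    The deletion is reported only when the true deleted-cell fraction
    reaches ``detection_limit``; the reported clonality is the true
    fraction plus small measurement noise, clipped into
    [detection_limit, 1].  Below the floor the deletion is cryptic and the
    call is negative.
    """
    true_frac = arch.deleted_fraction
    if true_frac < detection_limit or true_frac == 0.0:
        return False, None
    noisy = true_frac + rng.normal(0.0, clonality_noise_sd)
    return True, float(np.clip(noisy, detection_limit, 1.0))


def truth_stratum(
    truth_biallelic_fraction: float, n_mutations: int, params: SimParams
) -> str:
    if truth_biallelic_fraction > params.biallelic_hazard_threshold:
        return STRATUM_BIALLELIC
    return STRATUM_MONO if n_mutations > 0 else STRATUM_WT


@lru_cache(maxsize=None)
def _censor_scale(censor_rate: float) -> float:
    """Solve (1 - e^-x)/x = censor_rate for x.

    With event time T ~ Exp(lam) and an independent censoring time
    C ~ Uniform(0, u), the censoring probability P(C < T) equals
    (1 - e^-(lam u)) / (lam u); the root x = lam u sets the uniform scale
    that achieves the requested censoring fraction.
    """
    return float(brentq(lambda x: (1.0 - np.exp(-x)) / x - censor_rate, 1e-9, 1e6))


def _censored_draw(
    median: float, censor_rate: float, rng: np.random.Generator
) -> tuple[float, bool]:
    """Exponential event time under independent uniform censoring.

    Independence of the censoring time from the event time keeps the
    product-limit estimator unbiased for the stratum median.
    """
    lam = np.log(2.0) / median
    t = rng.exponential(1.0 / lam)
    if censor_rate <= 0.0:
        return float(t), True
    if censor_rate >= 1.0:
        return float(rng.uniform(0.0, t)), False
    c = rng.uniform(0.0, _censor_scale(censor_rate) / lam)
    if c < t:
        return float(c), False
    return float(t), True


def sample_survival(
    truth_biallelic_fraction: float,
    params: SimParams,
    rng: np.random.Generator,
    n_mutations: int = 1,
) -> tuple[float, bool]:
    """Exponential survival with a stratum-specific median.

    A fraction ``censor_rate`` of subjects is lost to independent uniform
    censoring before their event.
    """
    stratum = truth_stratum(truth_biallelic_fraction, n_mutations, params)
    return _censored_draw(params.hazard_medians[stratum], params.censor_rate, rng)


@dataclass(frozen=True)
class SingleCellDraw:
    """Single-cell genotyping of one architecture.

    ``true_mutant`` / ``true_total`` give each cell's mutant copy count per
    mutation and its locus copy number before dropout; ``obs_mutant`` /
    ``obs_total`` are the post-dropout observations (each allele retained
    independently with probability 1 - ado_rate).  ``biallelic`` flags
    cells with two inactivated alleles, computed before dropout.
    """

    true_mutant: np.ndarray  # (n_cells, n_mutations)
    true_total: np.ndarray  # (n_cells,)
    obs_mutant: np.ndarray
    obs_total: np.ndarray
    biallelic: np.ndarray  # (n_cells,) bool


def sample_single_cells(
    arch: ClonalArchitecture,
    n_cells: int,
    ado_rate: float,
    rng: np.random.Generator,
) -> SingleCellDraw:
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    fracs = np.array([s.fraction for s in arch.states])
    state_idx = rng.choice(len(arch.states), size=n_cells, p=fracs / fracs.sum())

    m = max(arch.n_mutations, 1)
    true_mut = np.zeros((n_cells, arch.n_mutations), dtype=int)
    true_tot = np.zeros(n_cells, dtype=int)
    bial = np.zeros(n_cells, dtype=bool)
    for k, s in enumerate(arch.states):
        sel = state_idx == k
        true_tot[sel] = s.total_copies
        for j in range(arch.n_mutations):
            true_mut[sel, j] = s.mutant_copies[j]
        bial[sel] = s.is_biallelic

    # each physical copy survives dropout independently; a mutant copy that
    # survives is observed mutant, a WT copy observed WT
    obs_tot = rng.binomial(true_tot, 1.0 - ado_rate)
    obs_mut = np.zeros_like(true_mut)
    for j in range(arch.n_mutations):
        # observed mutant copies: hypergeometric-like thinning, realised by
        # dropping each mutant copy independently then capping by obs_tot
        kept_mut = rng.binomial(true_mut[:, j], 1.0 - ado_rate)
        obs_mut[:, j] = np.minimum(kept_mut, obs_tot)
    return SingleCellDraw(
        true_mutant=true_mut,
        true_total=true_tot,
        obs_mutant=obs_mut,
        obs_total=obs_tot,
        biallelic=bial,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

#: disease-subtype frequencies among TP53-mutated myeloid neoplasms
_SUBTYPE_P = {
    Subtype.pAML: 0.312,
    Subtype.sAML: 0.109,
    Subtype.HR_MDS: 0.231,
    Subtype.LR_MDS: 0.241,
    Subtype.MDS_MPN: 0.105,
    Subtype.other: 0.002,
}

_EFFECT_P = {Effect.missense: 0.74, Effect.truncated: 0.15, Effect.other: 0.11}

_CANONICAL = ("R175H", "Y220C", "M237I", "R248Q", "R273H", "R282W")


def _draw_subtype(rng: np.random.Generator) -> Subtype:
    subtypes = list(_SUBTYPE_P)
    return subtypes[int(rng.choice(len(subtypes), p=list(_SUBTYPE_P.values())))]


def _draw_architecture(
    family: str, rng: np.random.Generator
) -> ClonalArchitecture:
    """Sample one architecture from the named family.

    Clone sizes are drawn so each family lands where its class name says:
    dominant biallelic clones exceed half the cells (VAF arithmetic forces
    the obligatory call), cryptic biallelic subclones stay below ~10% of
    cells with a combined VAF under the low-20s, and heterozygous clones
    span the full subclonal range.
    """
    if family == "WT":
        return arch_wild_type()
    if family == "monoallelic":
        if rng.random() < 0.85:
            return arch_heterozygous(rng.uniform(0.05, 0.90))
        # two independent monoallelic clones (subclonal mosaicism)
        f1 = rng.uniform(0.04, 0.30)
        f2 = rng.uniform(0.04, min(0.30, 0.98 - f1))
        return arch_mosaic_two_clones(f1, f2)
    if family == "cryptic_biallelic":
        b = rng.uniform(0.03, 0.10)
        h = rng.uniform(0.02, 0.22)
        return arch_cryptic_biallelic(b, h)
    if family == "dominant_biallelic":
        if rng.random() < 0.5:
            return arch_upd_homozygous(rng.uniform(0.58, 0.95))
        return arch_compound_heterozygous(rng.uniform(0.58, 0.95))
    if family == "del17p_involving":
        return arch_del17p_hemizygous(rng.uniform(0.50, 0.92))
    raise ValueError(f"unknown architecture family {family!r}")


def _make_variants(
    pid: str,
    arch: ClonalArchitecture,
    depth: float,
    rng: np.random.Generator,
    min_observable_vaf: float = 0.01,
) -> list[VariantCall]:
    variants = []
    for j in range(arch.n_mutations):
        obs = sample_bulk_vaf(arch, j, depth, rng)
        if obs < min_observable_vaf:
            continue  # below the calling floor of the sequencing pipeline
        effects = list(_EFFECT_P)
        effect = effects[int(rng.choice(len(effects), p=list(_EFFECT_P.values())))]
        protein = (
            str(rng.choice(_CANONICAL))
            if effect is Effect.missense and rng.random() < 0.69
            else None
        )
        variants.append(VariantCall(pid, effect, obs, protein))
    return variants


def simulate_cohort(params: SimParams) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a fully seeded cohort with its ground-truth table.

    Patient records contain only observables (called variants with noisy
    VAFs, cytogenetics subject to the detection floor, survival); the truth
    table records the architecture family, the true biallelic cell
    fraction, the hazard stratum, and the true number of hits per patient.
    """
    rng = np.random.default_rng(params.seed)
    families = list(params.class_mix)
    probs = np.array([params.class_mix[f] for f in families])
    probs = probs / probs.sum()

    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(params.n_patients):
        pid = f"S{i:05d}"
        family = families[int(rng.choice(len(families), p=probs))]
        arch = _draw_architecture(family, rng)
        variants = _make_variants(pid, arch, params.depth, rng)
        del_called, clonality = call_del17p(arch, params.del17p_detection_limit, rng)
        upd_called = arch.upd_fraction >= params.del17p_detection_limit
        complex_k = rng.random() < (0.72 if arch.n_mutations > 0 else 0.10)
        cyto = CytoRecord(
            patient_id=pid,
            del17p=del_called,
            del17p_clonality=clonality,
            upd17p=bool(upd_called),
            complex_karyotype=bool(complex_k),
        )
        os_months, os_event = sample_survival(
            arch.truth_biallelic_fraction, params, rng, n_mutations=arch.n_mutations
        )
        subtype = _draw_subtype(rng)
        records.append(
            PatientRecord(
                patient_id=pid,
                subtype=subtype,
                os_months=os_months,
                os_event=os_event,
                variants=tuple(variants),
                cyto=cyto,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "family": family,
                "stratum": truth_stratum(
                    arch.truth_biallelic_fraction, arch.n_mutations, params
                ),
                "biallelic_fraction": arch.truth_biallelic_fraction,
                "n_true_hits": arch.n_mutations + (1 if arch.deleted_fraction > 0 else 0),
                "deleted_fraction": arch.deleted_fraction,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "family",
            "stratum",
            "biallelic_fraction",
            "n_true_hits",
            "deleted_fraction",
        ],
    )
    return records, truth


def simulate_changepoint_cohort(
    n_patients: int,
    seed: int,
    changepoint: float = 0.25,
    wt_fraction: float = 0.4,
    depth: float = 500.0,
    censor_rate: float = 0.1,
    hazard_medians: Optional[dict[str, float]] = None,
    null: bool = False,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Cohort with a planted hazard change-point on the VAF axis.

    Mutated patients receive a true bulk VAF uniform on (0.02, 0.48); those
    above ``changepoint`` carry a biallelic architecture (a homozygous UPD
    clone of that size) and the biallelic-stratum hazard, those below carry
    a heterozygous clone (monoallelic hazard).  Wild-type patients fill the
    remaining ``wt_fraction``.  With ``null=True`` the hazard ignores VAF
    entirely (all mutated patients share the monoallelic median), giving
    the no-signal reference condition for the cutoff search.

    Every VAF stays below 50% so no patient is obligatory biallelic: the
    whole signal sits where the cutoff search has to find it.
    """
    medians = dict(_default_medians())
    if hazard_medians:
        medians.update(hazard_medians)
    params = SimParams(
        n_patients=n_patients,
        depth=depth,
        censor_rate=censor_rate,
        hazard_medians=medians,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(n_patients):
        pid = f"C{i:05d}"
        if rng.random() < wt_fraction:
            arch = arch_wild_type()
            stratum = STRATUM_WT
        else:
            target = rng.uniform(0.02, 0.48)
            if target > changepoint:
                arch = arch_upd_homozygous(target)  # expected VAF = target
                stratum = STRATUM_BIALLELIC
            else:
                arch = arch_heterozygous(2.0 * target)  # expected VAF = target
                stratum = STRATUM_MONO
        if null and arch.n_mutations > 0:
            stratum = STRATUM_MONO
        os_months, os_event = _censored_draw(medians[stratum], censor_rate, rng)
        variants = _make_variants(pid, arch, depth, rng)
        subtype = _draw_subtype(rng)
        records.append(
            PatientRecord(
                patient_id=pid,
                subtype=subtype,
                os_months=os_months,
                os_event=os_event,
                variants=tuple(variants),
                cyto=None,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "family": "changepoint",
                "stratum": stratum,
                "biallelic_fraction": arch.truth_biallelic_fraction,
                "n_true_hits": arch.n_mutations,
                "deleted_fraction": arch.deleted_fraction,
            }
        )
    return records, pd.DataFrame(truth_rows)
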
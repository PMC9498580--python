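"""Synthetic cohorts, predictor profiles, and interaction graphs with known
ground truth.

The generator emulates the structure of the study data so the triage,
aggregation, and network stages are testable without any external download:

* genotypes follow Hardy-Weinberg sampling at the specified allele
  frequency — autosomal dose ~ Binomial(2, AF) per patient; on the X
  chromosome females draw Binomial(2, AF) and males Bernoulli(AF),
  recorded as hemizygous;
* predictor profiles are drawn conditional on a ground-truth deleterious
  label (concordant by construction, with a configurable discordance rate
  that flips one predictor to exercise the 2-of-3 logic);
* graphs follow a planted-partition (stochastic block) model with edge
  confidences U(0.4, 0.95), returning the true block labels.

The default cohort mirrors the study: 11 patients, 9 male / 2 female, so
the allele-number denominators 22 (autosomal) and 13 (X) arise naturally.
A single root seed derives independent per-stage streams, so stages can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .errors import ValidationError
from .models import (
    CHROMOSOME_CLASSES,
    CONSEQUENCES,
    Cohort,
    PredictorProfile,
    VariantRecord,
)

DEFAULT_N_PATIENTS = 11
DEFAULT_N_MALE = 9
DISCORDANCE_RATE = 0.1


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator derived from a root seed and an integer key path."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class VariantSpec:
    """Ground truth for one simulated variant."""

    gene: str
    chromosome_class: str
    allele_freq: float
    true_deleterious: bool
    consequence: str = "missense"
    nt_change: Optional[str] = None
    panel: str = "motile"
    clinical_class: str = "VUS"

    def __post_init__(self):
        if self.chromosome_class not in CHROMOSOME_CLASSES:
            raise ValidationError(f"chromosome_class={self.chromosome_class!r}")
        if not (0.0 <= self.allele_freq <= 1.0):
            raise ValidationError(f"allele_freq={self.allele_freq} outside [0, 1]")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"consequence={self.consequence!r}")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Specification of a simulated cohort; the seed is mandatory."""

    seed: int
    n_patients: int = DEFAULT_N_PATIENTS
    n_male: int = DEFAULT_N_MALE
    variants: Tuple[VariantSpec, ...] = field(default_factory=tuple)
    discordance: float = DISCORDANCE_RATE

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        if not (0 <= self.n_male <= self.n_patients):
            raise ValidationError("n_male must lie in [0, n_patients]")
        if not (0.0 <= self.discordance <= 1.0):
            raise ValidationError("discordance must lie in [0, 1]")
        object.__setattr__(self, "variants", tuple(self.variants))

    def cohort(self) -> Cohort:
        """Patient ids P01.. with males first (sex composition is fixed, not drawn)."""
        patients = tuple(
            (f"P{i + 1:02d}", "male" if i < self.n_male else "female")
            for i in range(self.n_patients)
        )
        return Cohort(patients=patients)


def simulate_predictors(
    true_deleterious: bool,
    consequence: str,
    rng: np.random.Generator,
    discordance: float = DISCORDANCE_RATE,
) -> PredictorProfile:
    """Draw a predictor profile conditional on the ground-truth label.

    Deleterious missense truth: SIFT score U(0, 0.05) with label D, both
    PolyPhen2 sub-models U(0.9, 1) with label PD, MutationAssessor M or H.
    Benign truth: SIFT U(0.2, 1) label T, PolyPhen2 U(0, 0.3) label B,
    MutationAssessor N or L.  Loss-of-function classes draw CADD PHRED
    U(25, 45) (deleterious) vs U(5, 15) (benign).  With probability
    *discordance* one missense predictor (or the CADD band) is flipped.
    """
    flip = rng.random() < discordance
    if consequence == "missense":
        state = {"SIFT": true_deleterious, "PP2": true_deleterious,
                 "MA": true_deleterious}
        if flip:
            which = rng.choice(["SIFT", "PP2", "MA"])
            state[which] = not state[which]
        if state["SIFT"]:
            sift_label, sift_score = "D", float(rng.uniform(0.0, 0.05))
        else:
            sift_label, sift_score = "T", float(rng.uniform(0.2, 1.0))
        if state["PP2"]:
            pp2_label = "PD"
            div, var = rng.uniform(0.9, 1.0, size=2)
        else:
            pp2_label = "B"
            div, var = rng.uniform(0.0, 0.3, size=2)
        if state["MA"]:
            ma_label = str(rng.choice(["M", "H"]))
            ma_score = float(rng.uniform(2.0, 4.5))
        else:
            ma_label = str(rng.choice(["N", "L"]))
            ma_score = float(rng.uniform(-1.0, 1.9))
        return PredictorProfile(
            sift_label=sift_label,
            sift_score=sift_score,
            pp2_humdiv_label=pp2_label,
            pp2_humdiv_score=float(div),
            pp2_humvar_label=pp2_label,
            pp2_humvar_score=float(var),
            ma_label=ma_label,
            ma_score=ma_score,
        )
    label = true_deleterious != flip
    cadd = float(rng.uniform(25.0, 45.0) if label else rng.uniform(5.0, 15.0))
    return PredictorProfile(cadd_phred=cadd)


def simulate_genotypes(spec: SyntheticCohortSpec) -> List[VariantRecord]:
    """Simulate carrier records for every variant in *spec* under HWE.

    One record per carrier (dose >= 1), with zygosity set from the sampled
    dose and predictors drawn from an independent sub-stream.  Byte-identical
    across runs for a fixed seed.
    """
    cohort = spec.cohort()
    records: List[VariantRecord] = []
    for v_idx, variant in enumerate(spec.variants):
        geno_rng = _substream(spec.seed, 0, v_idx)
        pred_rng = _substream(spec.seed, 1, v_idx)
        nt_change = variant.nt_change or f"c.{100 * (v_idx + 1)}A>G"
        novel = variant.allele_freq == 0.0
        for patient_id, sex in cohort.patients:
            if variant.chromosome_class == "X" and sex == "male":
                dose = int(geno_rng.random() < variant.allele_freq)
                zygosity = "hemi" if dose else None
            else:
                dose = int(geno_rng.binomial(2, variant.allele_freq))
                zygosity = {1: "het", 2: "hom"}.get(dose)
            if not dose:
                continue
            records.append(
                VariantRecord(
                    patient_id=patient_id,
                    gene=variant.gene,
                    dbsnp="New" if novel else f"rs9{v_idx:07d}",
                    nt_change=nt_change,
                    consequence=variant.consequence,
                    aa_change=None,
                    predictors=simulate_predictors(
                        variant.true_deleterious,
                        variant.consequence,
                        pred_rng,
                        spec.discordance,
                    ),
                    allele_freq=None if novel else variant.allele_freq,
                    freq_scope="latino",
                    zygosity=zygosity,
                    chromosome_class=variant.chromosome_class,
                    inheritance="XL" if variant.chromosome_class == "X" else "AR",
                    panel=variant.panel,
                    clinical_class=variant.clinical_class,
                )
            )
    return records


def simulate_graph(
    n_blocks: int,
    block_size: int,
    p_within: float,
    p_between: float,
    seed: int,
) -> Tuple[nx.Graph, dict]:
    """Planted-partition graph with confidences U(0.4, 0.95) on present edges.

    Returns the graph and the true node -> block mapping.  Nodes are named
    ``B{block}N{index}`` so the labelling is self-describing.
    """
    for name, p in (("p_within", p_within), ("p_between", p_between)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name}={p} outside [0, 1]")
    rng = _substream(seed, 2)
    nodes = [
        (f"B{b:02d}N{i:02d}", b) for b in range(n_blocks) for i in range(block_size)
    ]
    graph = nx.Graph()
    graph.add_nodes_from(name for name, _ in nodes)
    truth = dict(nodes)
    for i, (u, bu) in enumerate(nodes):
        for v, bv in nodes[i + 1:]:
            p = p_within if bu == bv else p_between
            if rng.random() < p:
                graph.add_edge(u, v, confidence=float(rng.uniform(0.4, 0.95)))
    return graph, truth
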
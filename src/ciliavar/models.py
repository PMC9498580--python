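"""Domain types for candidate-gene variant triage in a small exome cohort.

The unit of analysis is one annotated variant observed in one patient
(:class:`VariantRecord`), carrying the in-silico predictor annotations
(:class:`PredictorProfile`) that the deleteriousness classifier consumes,
a reference-population allele frequency (gnomAD; Latino/Admixed-American
stratum unless flagged as global), zygosity, and a gene-panel assignment.
Cohort-level denominators (autosomal and X allele numbers) live in
:class:`Cohort`.

Interaction networks are plain :class:`networkx.Graph` objects whose edges
carry a ``confidence`` attribute in [0, 1]; :func:`validate_interaction_graph`
enforces the container invariants (no self-edges, confidences in range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .errors import ValidationError

# Controlled vocabularies -------------------------------------------------

SIFT_LABELS = frozenset({"D", "T"})
PP2_LABELS = frozenset({"B", "PD", "D"})
MA_LABELS = frozenset({"N", "L", "M", "H"})
LOFTOOL_LABELS = frozenset({"PD", "other"})
CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "inframe_indel"}
)
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice", "inframe_indel"})
ZYGOSITIES = frozenset({"het", "hom", "hemi"})
CHROMOSOME_CLASSES = frozenset({"autosomal", "X"})
INHERITANCE_MODES = frozenset({"AD", "AR", "XL", "XLD", "NR", "ND"})
PANELS = frozenset(
    {"tga_associated", "motile", "non_motile", "ciliogenesis_trafficking"}
)
CILIA_PANELS = frozenset({"motile", "non_motile", "ciliogenesis_trafficking"})
CLINICAL_CLASSES = frozenset(
    {"benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic", "unclassified"}
)
FREQ_SCOPES = frozenset({"latino", "global"})
SEXES = frozenset({"male", "female"})

NOVEL_MARKER = "New"


def _check_in(value, vocabulary, name, *, optional=False):
    if value is None:
        if optional:
            return
        raise ValidationError(f"{name} is mandatory")
    if value not in vocabulary:
        raise ValidationError(f"{name}={value!r} not in {sorted(vocabulary)}")


def _check_unit_interval(value, name):
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name}={value} outside [0, 1]")


@dataclass
class PredictorProfile:
    """In-silico predictor annotations for one variant.

    Missense variants are scored by SIFT, PolyPhen2 (HumDiv and HumVar
    sub-models) and MutationAssessor; loss-of-function and splice variants
    by CADD PHRED and/or LoF-Tool.  Every field is optional — tables print
    only what the annotation pipeline returned — but range invariants are
    enforced on whatever is present.
    """

    sift_label: Optional[str] = None
    sift_score: Optional[float] = None
    pp2_humdiv_label: Optional[str] = None
    pp2_humdiv_score: Optional[float] = None
    pp2_humvar_label: Optional[str] = None
    pp2_humvar_score: Optional[float] = None
    ma_label: Optional[str] = None
    ma_score: Optional[float] = None
    cadd_phred: Optional[float] = None
    loftool_label: Optional[str] = None
    loftool_score: Optional[float] = None

    def __post_init__(self):
        _check_in(self.sift_label, SIFT_LABELS, "sift_label", optional=True)
        _check_in(self.pp2_humdiv_label, PP2_LABELS, "pp2_humdiv_label", optional=True)
        _check_in(self.pp2_humvar_label, PP2_LABELS, "pp2_humvar_label", optional=True)
        _check_in(self.ma_label, MA_LABELS, "ma_label", optional=True)
        _check_in(self.loftool_label, LOFTOOL_LABELS, "loftool_label", optional=True)
        _check_unit_interval(self.sift_score, "sift_score")
        _check_unit_interval(self.pp2_humdiv_score, "pp2_humdiv_score")
        _check_unit_interval(self.pp2_humvar_score, "pp2_humvar_score")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"cadd_phred={self.cadd_phred} must be nonnegative")

    @property
    def has_sift(self) -> bool:
        return self.sift_label is not None or self.sift_score is not None

    @property
    def has_pp2(self) -> bool:
        return any(
            v is not None
            for v in (
                self.pp2_humdiv_label,
                self.pp2_humdiv_score,
                self.pp2_humvar_label,
                self.pp2_humvar_score,
            )
        )

    @property
    def has_ma(self) -> bool:
        return self.ma_label is not None or self.ma_score is not None


@dataclass
class VariantRecord:
    """One annotated variant observation in one patient.

    ``dbsnp`` is either an rsID or the literal novelty marker ``"New"``;
    novel variants have no reference allele frequency.  ``freq_not_found``
    marks the rare known variant whose frequency the reference database
    does not report (printed "NF" in the source tables) — the only case in
    which a non-novel record may lack a frequency.  ``freq_scope`` records
    whether the frequency is from the Latino/Admixed-American stratum or,
    where that is unavailable (asterisk dialect in the source), global.
    Unmodelled source columns (OMIM numbers, protein domains, ...) are
    carried verbatim in ``extra``.
    """

    patient_id: str
    gene: str
    dbsnp: str
    nt_change: str
    consequence: str
    predictors: PredictorProfile
    aa_change: Optional[str] = None
    allele_freq: Optional[float] = None
    freq_scope: str = "latino"
    freq_not_found: bool = False
    zygosity: str = "het"
    chromosome_class: str = "autosomal"
    inheritance: str = "NR"
    panel: str = "tga_associated"
    clinical_class: str = "unclassified"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("patient_id", "gene", "dbsnp", "nt_change"):
            if not getattr(self, name):
                raise ValidationError(f"{name} is mandatory and non-empty")
        _check_in(self.consequence, CONSEQUENCES, "consequence")
        _check_in(self.freq_scope, FREQ_SCOPES, "freq_scope")
        _check_in(self.zygosity, ZYGOSITIES, "zygosity")
        _check_in(self.chromosome_class, CHROMOSOME_CLASSES, "chromosome_class")
        _check_in(self.inheritance, INHERITANCE_MODES, "inheritance")
        _check_in(self.panel, PANELS, "panel")
        _check_in(self.clinical_class, CLINICAL_CLASSES, "clinical_class")
        _check_unit_interval(self.allele_freq, "allele_freq")
        if self.is_novel and self.allele_freq is not None:
            raise ValidationError(
                f"{self.gene} {self.nt_change}: novel variant must not carry a frequency"
            )
        if self.allele_freq is None and not self.is_novel and not self.freq_not_found:
            raise ValidationError(
                f"{self.gene} {self.nt_change}: known variant lacks a frequency "
                "(mark freq_not_found for an explicit NF cell)"
            )
        if self.zygosity == "hemi" and self.chromosome_class != "X":
            raise ValidationError(
                f"{self.gene} {self.nt_change}: hemizygous call on an autosome"
            )
        if self.consequence == "missense":
            p = self.predictors
            if not (p.has_sift or p.has_pp2 or p.has_ma):
                raise ValidationError(
                    f"{self.gene} {self.nt_change}: missense row carries none of "
                    "SIFT/PolyPhen2/MutationAssessor"
                )
        else:
            p = self.predictors
            if p.cadd_phred is None and p.loftool_label is None:
                raise ValidationError(
                    f"{self.gene} {self.nt_change}: {self.consequence} row carries "
                    "neither CADD PHRED nor LoF-Tool"
                )

    @property
    def is_novel(self) -> bool:
        return self.dbsnp == NOVEL_MARKER

    @property
    def allele_dose(self) -> int:
        """Alternate-allele copies this observation contributes (hemi counts 1)."""
        return 2 if self.zygosity == "hom" else 1


@dataclass(frozen=True)
class Cohort:
    """Patients with sexes; defines allele-number denominators.

    For an 11-patient cohort of 9 males and 2 females the autosomal allele
    number is 22 and the X allele number 2x2 + 9 = 13.
    """

    patients: tuple  # of (patient_id, sex)

    def __post_init__(self):
        ids = [pid for pid, _ in self.patients]
        if not ids:
            raise ValidationError("cohort must contain at least one patient")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient ids in cohort")
        for _, sex in self.patients:
            _check_in(sex, SEXES, "sex")
        object.__setattr__(self, "patients", tuple(self.patients))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_male(self) -> int:
        return sum(1 for _, sex in self.patients if sex == "male")

    @property
    def n_female(self) -> int:
        return sum(1 for _, sex in self.patients if sex == "female")

    @property
    def autosomal_allele_number(self) -> int:
        return 2 * self.n_patients

    @property
    def x_allele_number(self) -> int:
        return 2 * self.n_female + self.n_male

    def sex_of(self, patient_id: str) -> str:
        for pid, sex in self.patients:
            if pid == patient_id:
                return sex
        raise ValidationError(f"patient {patient_id!r} not in cohort")

    def allele_number(self, chromosome_class: str) -> int:
        _check_in(chromosome_class, CHROMOSOME_CLASSES, "chromosome_class")
        if chromosome_class == "X":
            return self.x_allele_number
        return self.autosomal_allele_number


@dataclass(frozen=True)
class GenePanel:
    """A named set of candidate genes."""

    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"panel {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


#: Weighted gene-interaction network: a networkx Graph whose edges carry a
#: ``confidence`` attribute in [0, 1].
InteractionGraph = nx.Graph


def new_interaction_graph(edges=(), nodes=()) -> nx.Graph:
    """Build an interaction graph from (u, v, confidence) triples.

    Self-edges are dropped (the node is kept); symmetric duplicates are
    collapsed keeping the maximum confidence.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, conf in edges:
        conf = float(conf)
        if not (0.0 <= conf <= 1.0):
            raise ValidationError(f"edge {u}-{v}: confidence {conf} outside [0, 1]")
        g.add_node(u)
        g.add_node(v)
        if u == v:
            continue
        if g.has_edge(u, v):
            conf = max(conf, g.edges[u, v]["confidence"])
        g.add_edge(u, v, confidence=conf)
    return g


def validate_interaction_graph(g: nx.Graph) -> None:
    """Raise :class:`ValidationError` if *g* breaks the container invariants."""
    if any(u == v for u, v in g.edges):
        raise ValidationError("interaction graph contains a self-edge")
    for u, v, data in g.edges(data=True):
        conf = data.get("confidence")
        if conf is None or not (0.0 <= conf <= 1.0):
            raise ValidationError(f"edge {u}-{v}: confidence {conf!r} outside [0, 1]")


# Result containers --------------------------------------------------------

RULES = frozenset(
    {"missense_two_of_three", "missense_novel_one", "lof_cadd", "lof_tool", "none"}
)


@dataclass(frozen=True)
class TriageCall:
    """Outcome of the composite deleteriousness classification for one record."""

    deleterious: bool
    abnormal_predictors: frozenset
    rule_fired: str
    notes: str = ""

    def __post_init__(self):
        _check_in(self.rule_fired, RULES, "rule_fired")
        if self.deleterious and self.rule_fired == "none":
            raise ValidationError("deleterious call must name the rule that fired")
        object.__setattr__(
            self, "abnormal_predictors", frozenset(self.abnormal_predictors)
        )


@dataclass(frozen=True)
class GeneGenotypeSummary:
    """Deleterious-genotype bookkeeping for one (patient, gene) pair."""

    patient_id: str
    gene: str
    n_deleterious_het: int
    n_deleterious_hom: int
    n_deleterious_hemi: int
    compound_het: bool

    def __post_init__(self):
        if self.compound_het and self.n_deleterious_het < 2:
            raise ValidationError(
                "compound heterozygosity requires >= 2 deleterious het variants"
            )


@dataclass(frozen=True)
class AggregationResult:
    """Cohort-level binomial statistic for one recurrent variant.

    ``point_prob`` is Pr(K = k) under Binomial(n, p_ref) — the headline
    number of the source analysis — and ``tail_prob`` is Pr(K >= k), the
    calibrated upper-tail alternative; both are always reported.  A novel
    variant has no reference frequency and yields ``computable=False`` with
    a reason, never a silent skip.
    """

    gene: str
    nt_change: str
    k: int
    n: int
    p_ref: Optional[float]
    freq_scope: Optional[str]
    point_prob: Optional[float]
    tail_prob: Optional[float]
    mode_used: str
    computable: bool = True
    reason: str = ""
    novel: bool = False
    x_linked: bool = False

    def __post_init__(self):
        if self.mode_used not in {"point", "upper_tail"}:
            raise ValidationError(f"mode_used={self.mode_used!r}")
        if self.computable:
            for name in ("p_ref", "point_prob", "tail_prob"):
                v = getattr(self, name)
                if v is None or not (0.0 <= v <= 1.0):
                    raise ValidationError(f"{name}={v!r} outside [0, 1]")
            if self.tail_prob < self.point_prob - 1e-12:
                raise ValidationError("upper tail must include the point mass")

    @property
    def headline(self) -> Optional[float]:
        if not self.computable:
            return None
        return self.point_prob if self.mode_used == "point" else self.tail_prob


@dataclass(frozen=True)
class SexContingency:
    """2x2 alt/ref-allele by male/female table with its exact-test p-value."""

    alt_male: int
    ref_male: int
    alt_female: int
    ref_female: int
    p_value: float

    def __post_init__(self):
        for name in ("alt_male", "ref_male", "alt_female", "ref_female"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p_value must lie in (0, 1]")

    @property
    def table(self):
        return [[self.alt_male, self.alt_female], [self.ref_male, self.ref_female]]


@dataclass(frozen=True)
class ClusterPartition:
    """A hard partition of graph nodes produced by Markov Clustering."""

    labels: dict  # node -> cluster index, contiguous from 0
    inflation: float
    iterations_run: int
    converged: bool

    def __post_init__(self):
        ids = sorted(set(self.labels.values()))
        if ids and ids != list(range(len(ids))):
            raise ValidationError("cluster indices must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self):
        """Clusters as a list of sorted node lists, indexed by cluster id."""
        out = [[] for _ in range(self.n_clusters)]
        for node, cid in self.labels.items():
            out[cid].append(node)
        return [sorted(members) for members in out]


@dataclass(frozen=True)
class EnrichmentResult:
    """Permutation interaction-enrichment outcome for one gene set."""

    node_set: frozenset
    observed_edges: int
    null_mean: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "node_set", frozenset(self.node_set))
        floor = 1.0 / (self.n_permutations + 1)
        if self.p_value < floor - 1e-12 or self.p_value > 1.0:
            raise ValidationError(
                f"p_value {self.p_value} outside [{floor}, 1] for "
                f"{self.n_permutations} permutations"
            )
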
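"""Synthetic immunoglobulin repertoire simulation.

Generates germline-derived variable-domain repertoires with somatic
hypermutation (SHM), fully resampled CDR3 loops, species-distinct framework-2
hallmark signatures, and a sequence-dependent thermostability signal — the
statistical structure that masked-LM training, infilling evaluation,
nativeness scoring, and fine-tuning all assume, with ground truth known by
construction.

The shipped scaffolds are hand-built, IMGT-numbered VH-like sequences (not
real IGHV alleles): species "vhh" carries the camelid hallmark FERF at IMGT
42/49/50/52 and species "human" the conventional VGLW, with additional
framework differences loosely mirroring the llama/human contrast.

SHM is modeled as independent per-position substitutions — no clonal lineage
structure, no indels — at a region-dependent rate (base rate times a hotspot
multiplier), with the substitution drawn from a row-stochastic 20x20 matrix
whose diagonal is zero. CDR3 is replaced wholesale: a length is sampled, then
residues i.i.d. from a composition distribution (junctional diversity without
D/J bookkeeping).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .io import AMINO_ACIDS, SequenceRecord
from .numbering import (REGION_BOUNDS, GermlineScaffold, UnnumberableError,
                        number_sequence, parse_label, region_of)
from .pssm import Pssm, sample_from_pssm  # noqa: F401  (re-exported)

logger = logging.getLogger("vhhlm")

AA = list(AMINO_ACIDS)
_AA_IDX = {a: i for i, a in enumerate(AA)}


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

def uniform_substitution_matrix() -> np.ndarray:
    """Uniform off-diagonal substitution matrix (every mutation changes the residue)."""
    m = np.full((20, 20), 1.0 / 19.0)
    np.fill_diagonal(m, 0.0)
    return m


@dataclasses.dataclass
class ShmConfig:
    """Somatic-hypermutation model: per-position substitution process."""

    base_rate: float = 0.03
    hotspot_multipliers: dict = dataclasses.field(
        default_factory=lambda: {"CDR1": 4.0, "CDR2": 4.0})
    substitution_matrix: np.ndarray = dataclasses.field(
        default_factory=uniform_substitution_matrix)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be in [0, 1]")
        if any(m < 0 for m in self.hotspot_multipliers.values()):
            raise ValueError("hotspot multipliers must be >= 0")
        sm = np.asarray(self.substitution_matrix, dtype=float)
        if sm.shape != (20, 20):
            raise ValueError("substitution_matrix must be 20x20")
        if not np.allclose(sm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("substitution_matrix rows must sum to 1")
        if np.any(np.diag(sm) != 0.0):
            raise ValueError("substitution_matrix diagonal must be 0")
        self.substitution_matrix = sm

    def rate_for(self, region: str) -> float:
        return min(1.0, self.base_rate * self.hotspot_multipliers.get(region, 1.0))


def default_cdr3_lengths() -> dict[int, float]:
    # roughly symmetric around 12, the middle of natural VHH CDR3 lengths
    w = {8: 5, 9: 8, 10: 12, 11: 15, 12: 16, 13: 15, 14: 12, 15: 9, 16: 8}
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def default_cdr3_composition() -> dict[str, float]:
    # loop-like composition: glycine/serine/tyrosine-rich, cysteine-poor
    w = {"G": 12, "S": 12, "Y": 12, "A": 10, "D": 9, "R": 9, "T": 6, "N": 5,
         "V": 5, "L": 4, "W": 4, "P": 3, "F": 3, "I": 2, "E": 2, "K": 1,
         "H": 1, "Q": 0.5, "M": 0.25, "C": 0.25}
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


@dataclasses.dataclass
class Cdr3Config:
    """CDR3 resampling model: sampled length, i.i.d. per-position composition."""

    length_distribution: dict = dataclasses.field(default_factory=default_cdr3_lengths)
    composition: dict | Pssm = dataclasses.field(default_factory=default_cdr3_composition)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.length_distribution.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("length_distribution must sum to 1")
        if any(not 3 <= k <= 30 for k in self.length_distribution):
            raise ValueError("CDR3 lengths must lie in [3, 30]")
        if isinstance(self.composition, dict):
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("composition must sum to 1")

    def composition_vector(self, pos_index: int) -> np.ndarray:
        if isinstance(self.composition, Pssm):
            i = min(pos_index, len(self.composition.positions) - 1)
            return self.composition.matrix[i]
        v = np.zeros(20)
        for a, p in self.composition.items():
            v[_AA_IDX[a]] = p
        return v


@dataclasses.dataclass
class PropertyModel:
    """Additive sequence -> property (melting temperature) model.

    value = intercept + sum over numbered residues of
    effect_weights[(base IMGT position, residue)] + Gaussian(0, noise_sd).
    Insertion labels ("109A") contribute through their base position.
    """

    effect_weights: dict = dataclasses.field(default_factory=dict)
    intercept: float = 62.0
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def expected_value(self, labels_and_residues: list[tuple[str, str]]) -> float:
        total = self.intercept
        for res, lab in labels_and_residues:
            base, _ = parse_label(lab)
            total += self.effect_weights.get((base, res), 0.0)
        return total


def default_property_model(seed: int = 0, noise_sd: float = 1.5) -> PropertyModel:
    """Thermostability model with CDR3-composition effects.

    Aromatic and proline residues in the loop stabilize, glycine and acidic
    residues destabilize — a caricature of real melting-temperature
    determinants, chosen so the signal is carried by sequence content that
    actually varies across a simulated repertoire.
    """
    per_residue = {"W": 2.0, "F": 1.5, "Y": 1.0, "P": 0.8, "V": 0.5,
                   "K": -0.8, "D": -1.0, "G": -1.2, "S": -0.5, "N": -0.4}
    lo, hi = REGION_BOUNDS["CDR3"]
    weights = {(pos, aa): w for pos in range(lo, hi + 1)
               for aa, w in per_residue.items()}
    return PropertyModel(effect_weights=weights, intercept=62.0,
                         noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# scaffold fixtures
# ---------------------------------------------------------------------------

def _spread(lo: int, hi: int, k: int) -> list[int]:
    """k IMGT positions inside [lo, hi]: fill from both ends (IMGT gap style)."""
    if k > hi - lo + 1:
        raise ValueError("region too short")
    head = math.ceil(k / 2)
    return list(range(lo, lo + head)) + list(range(hi - (k - head) + 1, hi + 1))


_SCAFFOLD_POSITIONS = (
    list(range(1, 27)) + _spread(27, 38, 8) + list(range(39, 56))
    + _spread(56, 65, 7) + list(range(66, 105)) + _spread(105, 117, 9)
    + list(range(118, 129))
)

# species bases; FW2 carries the hallmark residues at IMGT 42/49/50/52
_BASES = {
    "vhh": {
        "FW1": "QVQLVESGGGLVQAGGSLRLSCAASG",
        "CDR1": "RTFSSYAM",
        "FW2": "GSWFRQAPGKEREFVAA",   # F42 E49 R50 F52
        "CDR2": "INSGGGS",
        "FW3": "TYYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYC",
        "CDR3": "AADPYSSGW",
        "FW4": "WGQGTQVTVSS",
    },
    "human": {
        "FW1": "EVQLVESGGGLVQPGGSLRLSCAASG",
        "CDR1": "FTFSSYAM",
        "FW2": "GSWVRQAPGKGLEWVSA",   # V42 G49 L50 W52
        "CDR2": "ISGSGGS",
        "FW3": "TYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC",
        "CDR3": "ARDGYSSGY",
        "FW4": "WGQGTLVTVSS",
    },
}

# per-gene framework substitutions (IMGT position -> residue) and CDR swaps
_GENES = {
    "vhh": [
        ("VHH-1", {}, {}),
        ("VHH-2", {1: "E", 84: "N"}, {"CDR1": "RTFSNYAM", "CDR3": "AADRYGSGW"}),
        ("VHH-3", {5: "Q", 79: "K"}, {"CDR2": "INWGGGS", "CDR3": "AAGPYYSGW"}),
        ("VHH-4", {16: "A", 93: "T"}, {"CDR1": "RTFSRYGM", "CDR3": "AVDPYSSNW"}),
        ("VHH-5", {44: "G", 101: "H"}, {"CDR2": "INTGGGT", "CDR3": "AADLYSPGW"}),
    ],
    "human": [
        ("HVH-1", {}, {}),
        ("HVH-2", {1: "Q", 84: "S"}, {"CDR1": "FTFSDYAM", "CDR3": "ARDGYGSGY"}),
        ("HVH-3", {5: "L", 79: "R"}, {"CDR2": "ISYSGGS", "CDR3": "ARGGYYSGY"}),
        ("HVH-4", {16: "S", 93: "V"}, {"CDR1": "FTFSRYWM", "CDR3": "AKDGYSSNY"}),
        ("HVH-5", {44: "R", 101: "N"}, {"CDR2": "ISGSGST", "CDR3": "ARDVYSPGY"}),
    ],
}


def _build_scaffold(species: str, gene_id: str, fw_subs: dict, cdr_swaps: dict
                    ) -> GermlineScaffold:
    regions = dict(_BASES[species])
    regions.update(cdr_swaps)
    seq = "".join(regions[r] for r in
                  ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3", "FW4"))
    chars = list(seq)
    for pos, res in fw_subs.items():
        chars[_SCAFFOLD_POSITIONS.index(pos)] = res
    return GermlineScaffold(gene_id=gene_id, sequence="".join(chars),
                            imgt_numbers=list(_SCAFFOLD_POSITIONS), species=species)


def species_scaffolds(species: str) -> list[GermlineScaffold]:
    """The five shipped germline scaffolds for ``'vhh'`` or ``'human'``."""
    if species not in _GENES:
        raise ValueError(f"unknown species {species!r}; expected 'vhh' or 'human'")
    return [_build_scaffold(species, g, subs, swaps) for g, subs, swaps in _GENES[species]]


@dataclasses.dataclass
class SpeciesPair:
    germlines_a: list[GermlineScaffold]
    germlines_b: list[GermlineScaffold]
    shm_a: ShmConfig
    shm_b: ShmConfig
    cdr3_a: Cdr3Config
    cdr3_b: Cdr3Config


def make_species_pair(seed_a: int = 101, seed_b: int = 202) -> SpeciesPair:
    """Two germline sets with distinct FW2 hallmark signatures (FERF vs VGLW)."""
    return SpeciesPair(
        germlines_a=species_scaffolds("vhh"),
        germlines_b=species_scaffolds("human"),
        shm_a=ShmConfig(seed=seed_a),
        shm_b=ShmConfig(seed=seed_b),
        cdr3_a=Cdr3Config(seed=seed_a),
        cdr3_b=Cdr3Config(seed=seed_b),
    )


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_repertoire(germlines: list[GermlineScaffold], shm: ShmConfig,
                        cdr3: Cdr3Config, n: int, seed: int | None = None,
                        weights: list[float] | None = None,
                        species: str | None = None,
                        id_prefix: str = "sim") -> list[SequenceRecord]:
    """Draw ``n`` SHM-mutated, CDR3-resampled sequences from the germline set.

    ``weights`` are germline mixing proportions (uniform when omitted). The
    record keeps its true germline gene and the realized non-CDR3 mutation
    count. Deterministic given ``seed`` (falls back to ``shm.seed``).
    """
    if not germlines:
        raise ValueError("at least one germline scaffold is required")
    if n < 1:
        raise ValueError("n must be >= 1")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(germlines) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("weights must be a probability vector over germlines")
    else:
        w = np.full(len(germlines), 1.0 / len(germlines))
    rng = np.random.default_rng(shm.seed if seed is None else seed)

    lengths = sorted(cdr3.length_distribution)
    lprobs = np.array([cdr3.length_distribution[k] for k in lengths])
    sub = shm.substitution_matrix
    lo3, hi3 = REGION_BOUNDS["CDR3"]

    records: list[SequenceRecord] = []
    for i in range(n):
        g = int(rng.choice(len(germlines), p=w))
        sc = germlines[g]
        out: list[str] = []
        n_mut = 0
        for res, pos in zip(sc.sequence, sc.imgt_numbers):
            region = region_of(pos)
            if region == "CDR3":
                continue  # replaced wholesale below (in sequence order later)
            rate = shm.rate_for(region)
            if rate > 0 and rng.random() < rate:
                res = AA[int(rng.choice(20, p=sub[_AA_IDX[res]]))]
                n_mut += 1
            out.append((pos, res))
        L3 = int(rng.choice(lengths, p=lprobs)) if len(lengths) > 1 else lengths[0]
        cdr3_res = [AA[int(rng.choice(20, p=cdr3.composition_vector(j)))]
                    for j in range(L3)]
        # assemble in IMGT order: everything before CDR3, the loop, then FW4
        pre = "".join(r for p, r in out if p < lo3)
        post = "".join(r for p, r in out if p > hi3)
        records.append(SequenceRecord(
            id=f"{id_prefix}{i}",
            sequence=pre + "".join(cdr3_res) + post,
            species=species or sc.species,
            germline_gene=sc.gene_id,
            n_mutations=n_mut,
        ))
    return records


def simulate_property(records: list[SequenceRecord], model: PropertyModel,
                      scaffolds: list[GermlineScaffold]
                      ) -> list[tuple[str, float]]:
    """Assign each record a property value (°C) under the additive model.

    Unnumberable sequences are skipped with a warning. Values are also stored
    on the records' ``measurement`` field. Deterministic given ``model.seed``.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(model.seed)
    out: list[tuple[str, float]] = []
    for rec in records:
        noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
        try:
            ns = number_sequence(rec, scaffolds)
        except UnnumberableError as exc:
            logger.warning("skipping %s in property simulation: %s", rec.id, exc)
            continue
        value = model.expected_value(ns.positions) + noise
        rec.measurement = float(value)
        out.append((rec.id, float(value)))
    return out
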
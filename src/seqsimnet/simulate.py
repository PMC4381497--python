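"""Synthetic labelled amplicon communities with known ground truth.

The generator plants a set of species, each represented by a centroid
sequence, and emits V4-length amplicons as centroid copies with i.i.d.
per-site substitutions. Labels (site, habitat, epoch) are assigned under a
chosen dispersal scenario so that every downstream stage — similarity
filtering, thresholded networks, community detection, novelty detection and
the endemism tests — can be checked against planted truth.

Design of the centroid cloud
----------------------------
Non-novel centroids are grown as a random recursive chain: each new centroid
mutates a uniformly chosen earlier one at a rate slightly above the minimum
between-species divergence (rejection sampling enforces the minimum). The
resulting species cloud has parent–child identities of roughly 86–88% and
all other pairs well below 80%, so similarity networks show the two regimes
the method exploits: one sparse giant component at the 85% threshold
(species mix, and label structure becomes testable by assortativity), and
clean one-species components at thresholds of 90% and above.

Novel species — planted to be undiscovered diversity — are independent
uniform-random sequences rejection-checked to be below the 95% identity
criterion against every cultured centroid; in practice they are far more
divergent, forming isolated components at every threshold.

The mutation model is substitution-only by default so percent identity has
a closed-form expectation: two members of the same species differ per site
with probability ``2 d (1 - d) + (2/3) d**2`` at divergence ``d``. An
optional indel rate exists for robustness checks and defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import HABITATS, SequenceRecord

DISPERSAL_MODES = ("endemic", "cosmopolitan", "habitat_structured")

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ScenarioConfig:
    """Parameters of a planted-community scenario.

    Attributes
    ----------
    n_species : int
        Number of planted species centroids.
    seqs_per_species : int
        New-survey sequences emitted per species.
    seq_length : int
        Amplicon length in nucleotides (default 380, V4-like).
    within_species_divergence : float
        Per-site substitution probability applied to each member copy
        (default 0.005, i.e. ~99% expected within-species identity).
    between_species_divergence : float
        Minimum pairwise centroid divergence enforced by rejection
        sampling (default 0.10: species separate at thresholds >= 90%,
        related pairs still connect at 85%).
    n_sites : int
        Number of sampling sites (default 8).
    habitats : tuple of str
        Habitat label set (default subsurface/DCM/sediment).
    dispersal_mode : str
        ``endemic`` (each species confined to one site),
        ``cosmopolitan`` (site drawn uniformly per sequence) or
        ``habitat_structured`` (a fraction of species confined to one
        habitat, sites uniform).
    frac_cultured : float
        Fraction of species that get an epoch=cultured reference sequence
        (the unmutated centroid).
    frac_novel : float
        Fraction of species planted as novel: no cultured reference and
        centroid below the 95% identity criterion against every cultured
        centroid. For the novelty-recovery guarantee to be exact,
        ``frac_cultured + frac_novel`` should equal 1, otherwise the
        leftover species are indistinguishable from novel ones.
    confined_fraction : float
        In habitat_structured mode, fraction of species confined to
        ``confined_habitat``.
    prior_env_per_species : int
        Earlier-survey (epoch=prior_env) copies emitted per non-novel
        species; carries no site/habitat labels.
    novel_identity_cutoff : float
        Percent-identity criterion used when rejecting novel centroids
        against the cultured pool (default 95).
    indel_rate : float
        Per-site insertion/deletion probability for member copies
        (default 0: substitution-only).
    seed : int
        RNG seed; fixed seed gives byte-identical output.
    """

    n_species: int = 40
    seqs_per_species: int = 20
    seq_length: int = 380
    within_species_divergence: float = 0.005
    between_species_divergence: float = 0.10
    n_sites: int = 8
    habitats: tuple = HABITATS
    dispersal_mode: str = "endemic"
    frac_cultured: float = 0.5
    frac_novel: float = 0.5
    confined_fraction: float = 0.5
    confined_habitat: str = "sediment"
    prior_env_per_species: int = 0
    novel_identity_cutoff: float = 95.0
    indel_rate: float = 0.0
    molecule: str = "DNA"
    seed: int = 0
    max_rejection_tries: int = 200

    def validate(self) -> None:
        if self.n_species < 1 or self.seqs_per_species < 1 or self.seq_length < 1:
            raise ValueError("counts must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("within_species_divergence", "between_species_divergence",
                     "frac_cultured", "frac_novel", "confined_fraction", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersal_mode not in DISPERSAL_MODES:
            raise ValueError(f"unknown dispersal_mode {self.dispersal_mode!r}")
        if self.frac_cultured + self.frac_novel > 1.0 + 1e-9:
            raise ValueError("frac_cultured + frac_novel must not exceed 1")
        if self.confined_habitat not in self.habitats:
            raise ValueError("confined_habitat must be one of habitats")

    @property
    def sites(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]


@dataclass
class TruthTable:
    """Ground truth of a generated dataset.

    ``records`` maps every emitted sequence to its planted species
    (columns: id, truth_species, dispersal_mode); ``species`` describes
    each planted species (novel/cultured flags, confinement labels).
    """

    records: pd.DataFrame
    species: pd.DataFrame

    def write(self, records_path, species_path=None) -> None:
        self.records.to_csv(records_path, sep="\t", index=False)
        if species_path is not None:
            self.species.to_csv(species_path, sep="\t", index=False)

    @staticmethod
    def read(records_path, species_path=None) -> "TruthTable":
        rec = pd.read_csv(records_path, sep="\t")
        spp = pd.read_csv(species_path, sep="\t") if species_path else pd.DataFrame()
        return TruthTable(records=rec, species=spp)


def expected_within_identity(divergence: float) -> float:
    """Exact expected %identity between two same-species members.

    Each member substitutes every site independently with probability ``d``
    (uniformly to one of the three other bases); two members then differ
    per site with probability ``2 d (1-d) + (2/3) d**2``.
    """
    d = divergence
    p_diff = 2 * d * (1 - d) + (2.0 / 3.0) * d * d
    return 100.0 * (1.0 - p_diff)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=length)]


def _mutate_subs(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` (always to a new base)."""
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    n = int(mask.sum())
    if n:
        # shift by 1..3 within the alphabet => guaranteed different base
        idx = np.searchsorted(_ALPHABET, seq[mask])
        shift = rng.integers(1, 4, size=n)
        out[mask] = _ALPHABET[(idx + shift) % 4]
    return out


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    keep = rng.random(seq.size) >= rate  # deletions
    out = seq[keep]
    n_ins = rng.binomial(seq.size, rate)
    if n_ins:
        pos = np.sort(rng.integers(0, out.size + 1, size=n_ins))
        out = np.insert(out, pos, _ALPHABET[rng.integers(0, 4, size=n_ins)])
    if out.size == 0:  # pathological rates; keep records valid
        out = _random_seq(rng, 1)
    return out


def _divergence(a: np.ndarray, b: np.ndarray) -> float:
    """Hamming divergence of two equal-length encoded sequences."""
    return float(np.mean(a != b))


def _grow_centroids(cfg: ScenarioConfig, rng: np.random.Generator,
                    n_linked: int, n_novel: int) -> tuple[list, list]:
    """Generate centroid sequences: a mutation chain plus isolated novels."""
    step = min(1.0, 1.3 * cfg.between_species_divergence)
    root = _random_seq(rng, cfg.seq_length)
    linked: list[np.ndarray] = []
    for i in range(n_linked):
        parent = root if i == 0 else linked[int(rng.integers(i))]
        for _ in range(cfg.max_rejection_tries):
            cand = _mutate_subs(parent, step, rng)
            if all(_divergence(cand, c) >= cfg.between_species_divergence
                   for c in linked):
                linked.append(cand)
                break
        else:
            raise RuntimeError(
                "rejection sampling failed: between_species_divergence "
                f"{cfg.between_species_divergence} is incompatible with "
                f"seq_length {cfg.seq_length} / n_species {cfg.n_species}"
            )
    n_cultured = int(round(cfg.frac_cultured * cfg.n_species))
    cultured_pool = linked[:n_cultured]
    novel: list[np.ndarray] = []
    for _ in range(n_novel):
        for _ in range(cfg.max_rejection_tries):
            cand = _random_seq(rng, cfg.seq_length)
            ok = all(_divergence(cand, c) >= cfg.between_species_divergence
                     for c in linked + novel)
            ok = ok and all(
                100.0 * (1.0 - _divergence(cand, c)) < cfg.novel_identity_cutoff
                for c in cultured_pool
            )
            if ok:
                novel.append(cand)
                break
        else:
            raise RuntimeError(
                "rejection sampling failed while planting novel species; "
                "relax novel_identity_cutoff or divergence settings"
            )
    return linked, novel


def generate_dataset(config: ScenarioConfig) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate a labelled dataset plus its ground-truth table.

    Returns
    -------
    records : list of SequenceRecord
        Cultured references (unmutated centroids, no site/habitat),
        optional prior-survey copies, and new-survey members with
        scenario-dependent site/habitat labels.
    truth : TruthTable
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_novel = int(round(cfg.frac_novel * cfg.n_species))
    n_cultured = int(round(cfg.frac_cultured * cfg.n_species))
    n_linked = cfg.n_species - n_novel

    linked, novel = _grow_centroids(cfg, rng, n_linked, n_novel)
    centroids = linked + novel
    species_ids = [f"sp{i + 1:03d}" for i in range(cfg.n_species)]
    is_novel = [i >= n_linked for i in range(cfg.n_species)]
    has_culture = [i < n_cultured for i in range(cfg.n_species)]

    sites = cfg.sites
    habitats = list(cfg.habitats)
    n_confined = int(round(cfg.confined_fraction * cfg.n_species))
    confined = np.zeros(cfg.n_species, dtype=bool)
    if cfg.dispersal_mode == "habitat_structured" and n_confined:
        confined[rng.permutation(cfg.n_species)[:n_confined]] = True

    # per-species fixed labels where the mode demands them
    species_site = [None] * cfg.n_species
    species_habitat = [None] * cfg.n_species
    if cfg.dispersal_mode == "endemic":
        for i in range(cfg.n_species):
            species_site[i] = sites[int(rng.integers(cfg.n_sites))]
            species_habitat[i] = habitats[int(rng.integers(len(habitats)))]
    elif cfg.dispersal_mode == "habitat_structured":
        for i in range(cfg.n_species):
            if confined[i]:
                species_habitat[i] = cfg.confined_habitat

    records: list[SequenceRecord] = []
    truth_rows = []

    def emit(rec: SequenceRecord, sp: str) -> None:
        records.append(rec)
        truth_rows.append({"id": rec.id, "truth_species": sp,
                           "dispersal_mode": cfg.dispersal_mode})

    def member_seq(centroid: np.ndarray) -> str:
        s = _mutate_subs(centroid, cfg.within_species_divergence, rng)
        s = _apply_indels(s, cfg.indel_rate, rng)
        return s.tobytes().decode("ascii")

    for i, sp in enumerate(species_ids):
        centroid = centroids[i]
        if has_culture[i]:
            emit(SequenceRecord(id=f"ref_{sp}",
                                sequence=centroid.tobytes().decode("ascii"),
                                molecule=cfg.molecule, epoch="cultured",
                                truth_species=sp), sp)
        if not is_novel[i]:
            for j in range(cfg.prior_env_per_species):
                emit(SequenceRecord(id=f"{sp}_p{j + 1:03d}",
                                    sequence=member_seq(centroid),
                                    molecule=cfg.molecule, epoch="prior_env",
                                    truth_species=sp), sp)
        for j in range(cfg.seqs_per_species):
            if cfg.dispersal_mode == "endemic":
                site, habitat = species_site[i], species_habitat[i]
            elif cfg.dispersal_mode == "cosmopolitan":
                site = sites[int(rng.integers(cfg.n_sites))]
                habitat = habitats[int(rng.integers(len(habitats)))]
            else:  # habitat_structured
                site = sites[int(rng.integers(cfg.n_sites))]
                habitat = (species_habitat[i] if confined[i]
                           else habitats[int(rng.integers(len(habitats)))])
            emit(SequenceRecord(id=f"{sp}_m{j + 1:03d}", sequence=member_seq(centroid),
                                molecule=cfg.molecule, epoch="new_survey",
                                site=site, habitat=habitat,
                                truth_species=sp), sp)

    species_df = pd.DataFrame({
        "species": species_ids,
        "novel": is_novel,
        "cultured_reference": has_culture,
        "confined": list(confined),
        "site": species_site,
        "habitat": species_habitat,
        "dispersal_mode": cfg.dispersal_mode,
    })
    truth = TruthTable(records=pd.DataFrame(truth_rows), species=species_df)
    return records, truth
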
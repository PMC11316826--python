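"""Synthetic mock communities, classifier profiles, taxonomies and reads.

The generator emulates the statistical structure the evaluation assumes,
so the whole pipeline can be exercised offline:

* ground truths with even, staggered, or logarithmic compositions (the
  three composition types of real commercial/consortium mocks; the
  logarithmic type steps down by a factor of ten per species);
* classifier profiles with planted false negatives (each truth taxon
  independently missed with probability ``fn_prob``), planted false
  positives (off-truth species at heavy-tailed low abundances), lognormal
  multiplicative abundance noise, and an unclassified read fraction;
* mini NCBI-style taxdump file sets, including synthetic merged and
  deleted taxids, loadable by the taxonomy module;
* FASTQ read sets with lognormal lengths and Gaussian per-read quality.

Simulation is at profile level: the system under test is the evaluation
framework, not any classifier's k-mer or alignment behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from dmcbench.profile_io import (
    GroundTruth,
    GroundTruthEntry,
    Profile,
    ProfileEntry,
)
from dmcbench.readstats import ReadRecord, write_fastq
from dmcbench.taxonomy import TaxonomyRef

__all__ = [
    "SimulationSpec",
    "make_truth",
    "simulate_classifier_profile",
    "simulate_reads",
    "make_mini_taxonomy",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated classifier-vs-mock experiment.

    Defaults describe a clean eight-species even mock (the canonical
    commercial standard) classified without error; tests and experiments
    turn individual knobs.
    """

    n_species: int = 8
    distribution: str = "even"  # even | staggered | log
    fn_prob: float = 0.0
    n_fp: int = 0
    fp_weight_scale: float = 0.001
    noise_cv: float = 0.0
    unclassified_frac: float = 0.0
    seed: int = 0
    sequencing_depth: int = 100_000

    def __post_init__(self) -> None:
        if self.distribution not in ("even", "staggered", "log"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        for name in ("fn_prob", "unclassified_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_species < 1 or self.n_fp < 0 or self.noise_cv < 0:
            raise ValueError("counts must be >= 0 (n_species >= 1), noise_cv >= 0")


def _species_nodes(ref: TaxonomyRef) -> list:
    return sorted(
        (n for n in ref.nodes.values() if n.rank == "species"), key=lambda n: n.taxid
    )


def make_truth(spec: SimulationSpec, ref: TaxonomyRef) -> GroundTruth:
    """Draw a ground truth of ``spec.n_species`` species from a taxonomy.

    even: equal fractions. log: fractions proportional to 10^-i. staggered:
    seeded distinct magnitudes spanning at least two orders, normalized.
    Genome lengths are drawn from 1.5-8 Mb (typical bacterial range).
    Deterministic for a fixed spec.
    """
    species = _species_nodes(ref)
    if len(species) < spec.n_species:
        raise ValueError(
            f"taxonomy has {len(species)} species, need {spec.n_species}"
        )
    rng = np.random.default_rng(spec.seed)
    chosen_idx = rng.choice(len(species), size=spec.n_species, replace=False)
    chosen = [species[i] for i in sorted(chosen_idx)]
    n = spec.n_species
    if spec.distribution == "even":
        fracs = np.full(n, 1.0 / n)
    elif spec.distribution == "log":
        raw = np.power(10.0, -np.arange(n, dtype=float))
        fracs = raw / raw.sum()
    else:  # staggered
        exponents = np.sort(rng.uniform(0.0, 2.5, size=n))
        exponents[0] = 0.0
        if n > 1:
            exponents[-1] = max(exponents[-1], 2.0)  # span >= 2 orders
        raw = np.power(10.0, -exponents)
        rng.shuffle(raw)
        fracs = raw / raw.sum()
    lengths = rng.integers(1_500_000, 8_000_000, size=n)
    entries = [
        GroundTruthEntry(
            taxid=node.taxid,
            name=node.scientific_name,
            fraction=float(f),
            genome_length=int(L),
        )
        for node, f, L in zip(chosen, fracs, lengths)
    ]
    # float dust can push the sum outside the 1e-6 gate; repair on the last entry
    drift = 1.0 - sum(e.fraction for e in entries)
    if entries and abs(drift) > 0:
        last = entries[-1]
        entries[-1] = GroundTruthEntry(
            taxid=last.taxid, name=last.name,
            fraction=last.fraction + drift, genome_length=last.genome_length,
        )
    return GroundTruth(dmc_id=f"sim_{spec.distribution}_{n}sp_seed{spec.seed}", entries=entries)


def simulate_classifier_profile(
    truth: GroundTruth, spec: SimulationSpec, ref: TaxonomyRef
) -> Profile:
    """Simulate one classifier's output for a mock community.

    Each truth taxon is dropped with probability ``fn_prob``; survivors get
    weight = truth fraction x lognormal noise with coefficient of variation
    ``noise_cv`` (expectation 1, exactly 1 at cv=0). ``n_fp`` off-truth
    species are added with weights ``fp_weight_scale`` x a log-uniform draw
    spanning three decades (occasional high-abundance false positives, as
    real read classifiers produce). Classified weights are scaled so that
    ``unclassified_frac`` of total read mass stays unclassified; counts are
    materialized at ``sequencing_depth`` reads.
    """
    rng = np.random.default_rng(spec.seed)
    truth_taxids = {e.taxid for e in truth.entries}
    weights: dict[int, float] = {}

    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    else:
        sigma = 0.0
    for entry in truth.entries:
        if rng.random() < spec.fn_prob:
            continue
        factor = 1.0 if sigma == 0.0 else float(rng.lognormal(-sigma * sigma / 2.0, sigma))
        weights[entry.taxid] = (entry.fraction if entry.fraction is not None else 1.0) * factor

    if spec.n_fp > 0:
        decoys = [n for n in _species_nodes(ref) if n.taxid not in truth_taxids]
        if len(decoys) < spec.n_fp:
            raise ValueError(
                f"taxonomy offers {len(decoys)} off-truth species, need {spec.n_fp}"
            )
        idx = rng.choice(len(decoys), size=spec.n_fp, replace=False)
        for i in sorted(idx):
            node = decoys[i]
            weights[node.taxid] = spec.fp_weight_scale * float(
                np.power(10.0, rng.uniform(-1.5, 1.5))
            )

    profile = Profile(
        sample_id=truth.dmc_id,
        classifier_id=f"sim_classifier_seed{spec.seed}",
    )
    depth = spec.sequencing_depth
    unclassified = spec.unclassified_frac
    profile.unclassified_fraction = unclassified
    profile.unclassified_count = int(round(unclassified * depth))
    if weights:
        total = sum(weights.values())
        classified_scale = 1.0 - unclassified
        for taxid in sorted(weights):
            node = ref.nodes[taxid]
            frac = weights[taxid] / total * classified_scale
            profile.entries.append(
                ProfileEntry(
                    taxid=taxid,
                    name=node.scientific_name,
                    rank=node.rank,
                    count=int(round(frac * depth)),
                    fraction=frac,
                )
            )
    return profile


def simulate_reads(
    n_reads: int,
    length_params: tuple[float, float] = (8.4, 0.6),
    quality_params: tuple[float, float] = (12.0, 3.0),
    seed: int = 0,
    path: Optional[str | Path] = None,
) -> list[ReadRecord]:
    """Generate nanopore-like reads; optionally write them as FASTQ.

    Lengths are lognormal (``length_params`` = mean and sd of log length in
    bases; defaults give a ~4.5 kb median). Each read draws one Gaussian
    quality value (``quality_params``, Phred), clipped to [0, 60] and applied
    to all its bases, so at sd 0 every read's mean quality equals the mean
    parameter exactly. Bases are uniform A/C/G/T. Deterministic under seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    mu, sigma = length_params
    qmean, qsd = quality_params
    lengths = np.maximum(1, rng.lognormal(mu, sigma, size=n_reads).astype(int))
    read_quals = np.clip(np.round(rng.normal(qmean, qsd, size=n_reads)), 0, 60).astype(int)
    alphabet = np.array(list("ACGT"))
    reads = []
    for i in range(n_reads):
        L = int(lengths[i])
        seq = "".join(alphabet[rng.integers(0, 4, size=L)])
        reads.append(
            ReadRecord(
                read_id=f"sim_read_{seed}_{i:06d}",
                sequence=seq,
                qualities=(int(read_quals[i]),) * L,
            )
        )
    if path is not None:
        write_fastq(reads, path)
    return reads


def make_mini_taxonomy(
    truth_species: Sequence[str],
    n_decoys: int = 0,
    n_merged: int = 0,
    n_deleted: int = 0,
    seed: int = 0,
    out_dir: str | Path = ".",
    strains_per_species: int = 0,
) -> dict[str, Path]:
    """Emit a mini taxdump file set (nodes/names/merged/delnodes).

    Contains a root, one genus per distinct genus word and one species node
    per listed species name, plus ``n_decoys`` generated decoy species under
    their own genera, ``n_merged`` synthetic old->current taxid pairs
    (targets drawn among the species), ``n_deleted`` deleted ids, and
    optionally strain nodes under each species. Files follow the standard
    pipe-delimited dump dialect and load with ``load_taxonomy``.
    Deterministic for fixed arguments.
    """
    if n_decoys < 0 or n_merged < 0 or n_deleted < 0 or strains_per_species < 0:
        raise ValueError("counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    nodes: list[tuple[int, int, str]] = [(1, 1, "no rank")]
    names: list[tuple[int, str]] = [(1, "root")]
    genus_ids: dict[str, int] = {}
    species_ids: list[int] = []
    next_id = 10

    def add_genus(genus_name: str) -> int:
        nonlocal next_id
        if genus_name not in genus_ids:
            genus_ids[genus_name] = next_id
            nodes.append((next_id, 1, "genus"))
            names.append((next_id, genus_name))
            next_id += 1
        return genus_ids[genus_name]

    def add_species(name: str) -> int:
        nonlocal next_id
        genus_name = name.split()[0]
        gid = add_genus(genus_name)
        sid = next_id
        nodes.append((sid, gid, "species"))
        names.append((sid, name))
        species_ids.append(sid)
        next_id += 1
        for s in range(strains_per_species):
            nodes.append((next_id, sid, "strain"))
            names.append((next_id, f"{name} strain {s + 1}"))
            next_id += 1
        return sid

    for name in truth_species:
        add_species(name)
    for d in range(n_decoys):
        add_species(f"Decoyus{d + 1:03d} species{d + 1:03d}")

    merged: list[tuple[int, int]] = []
    if n_merged:
        if not species_ids:
            raise ValueError("cannot plant merged ids without species")
        targets = rng.choice(species_ids, size=n_merged, replace=n_merged > len(species_ids))
        base = 9_000_000
        merged = [(base + i, int(t)) for i, t in enumerate(targets)]
    deleted = [9_500_000 + i for i in range(n_deleted)]

    paths = {
        "nodes": out_dir / "nodes.dmp",
        "names": out_dir / "names.dmp",
        "merged": out_dir / "merged.dmp",
        "delnodes": out_dir / "delnodes.dmp",
    }
    with open(paths["nodes"], "w", encoding="utf-8", newline="") as fh:
        for taxid, parent, rank in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(paths["names"], "w", encoding="utf-8", newline="") as fh:
        for taxid, name in names:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    with open(paths["merged"], "w", encoding="utf-8", newline="") as fh:
        for old, new in merged:
            fh.write(f"{old}\t|\t{new}\t|\n")
    with open(paths["delnodes"], "w", encoding="utf-8", newline="") as fh:
        for taxid in deleted:
            fh.write(f"{taxid}\t|\n")
    return paths
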
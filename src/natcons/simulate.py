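"""Synthetic multi-species expression data with known ground truth.

The generator emulates the design of a three-species (human/mouse/rat)
exon-array study run twice per sample — once with standard labeling (sense)
and once with a strand-flipping protocol (antisense) — over nine shared
tissues with two technical replicates.  Everything downstream of array
normalization is emulated: log2 intensity matrices, exon sequences diverged
from common ancestors, a HomoloGene-style homology table, BED transcript
annotations, and RefSeq/EST-like reference databases.  Every generated
probeset carries ground truth (conservation weight, spiked tissue, novelty
flag, dual-strand-overlap flag), so each pipeline stage can be scored
exactly.

Expression model (all on the log2 scale).  For an ortholog group with
conservation weight ``alpha`` and shared per-tissue latent vector ``b``,
each species' deviation from the protocol mean is

    dev = alpha * b + (1 - alpha) * u + eps,

with ``u`` an independent per-species latent draw and ``eps`` Gaussian noise
of sd ``noise_sd``.  ``alpha = 1`` with no noise gives identical profiles
across species; ``alpha = 0`` gives independent ones; the cross-species
profile correlation rises monotonically with ``alpha``.  Antisense values at
the same locus share a fraction ``sense_antisense_rho`` of the standardized
sense deviation, giving a per-tissue sense-antisense correlation of about
``rho`` across probesets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "DEFAULT_TISSUES",
    "mutate_sequence",
    "simulate_profile_pair",
    "simulate_profile_pairs",
    "simulate_tissue_panel",
    "simulate_dataset",
    "write_dataset",
]

DEFAULT_TISSUES = (
    "brain", "heart", "kidney", "liver", "lung",
    "spleen", "ovary", "testes", "thymus",
)
DEFAULT_SPECIES = ("human", "mouse", "rat")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_species: int = 3
    species: tuple[str, ...] = DEFAULT_SPECIES
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    extra_tissues: tuple[str, ...] = ()  # e.g. ("embryo",): present but non-orthologous
    n_ortholog_groups: int = 200
    n_unpaired_probesets: int = 100
    alpha_sense: float = 0.8
    alpha_antisense: float = 0.4
    alpha_jitter: float = 0.1  # per-locus conservation spread, shared across strands
    latent_sd: float = 1.0
    noise_sd: float = 0.5
    background_mean: float = 6.0
    background_sd: float = 0.2
    expressed_mean: float = 8.0
    antisense_offset: float = -1.0  # antisense arrays report lower levels
    frac_tissue_specific: float = 0.1  # of unpaired probesets
    spike_magnitude: float = 3.0
    sense_antisense_rho: float = 0.5
    substitution_rate: float = 0.05
    seq_length: int = 150
    frac_novel: float = 0.1
    frac_dual_overlap: float = 0.05
    n_replicates: int = 2
    replicate_sd: float = 0.25
    intensity_range: tuple[float, float] = (0.5, 15.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "alpha_sense", "alpha_antisense", "frac_tissue_specific",
            "frac_novel", "frac_dual_overlap", "substitution_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.sense_antisense_rho <= 1.0:
            raise ValueError("sense_antisense_rho must be in [-1, 1]")
        for name in ("noise_sd", "latent_sd", "background_sd", "replicate_sd", "alpha_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_species", "n_ortholog_groups", "n_unpaired_probesets",
                     "n_replicates", "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_species > len(self.species):
            raise ValueError("not enough species names for n_species")
        if self.alpha_sense < self.alpha_antisense:
            raise ValueError(
                "alpha_sense must be >= alpha_antisense (sense profiles are the "
                "more conserved ones in the emulated design)"
            )
        self.species = tuple(self.species[: self.n_species])

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth: one row per generated probeset, plus per-group weights.

    ``probesets`` columns: species, probeset, group_id ('' when unpaired),
    spiked_tissue ('' when none), novel, dual_overlap.  ``groups`` columns:
    group_id, alpha_sense, alpha_antisense.
    """

    probesets: pd.DataFrame
    groups: pd.DataFrame

    def novel_set(self, species: str) -> set[str]:
        t = self.probesets
        return set(t.loc[(t["species"] == species) & t["novel"], "probeset"])

    def spiked_map(self, species: str) -> dict[str, str]:
        t = self.probesets
        sub = t[(t["species"] == species) & (t["spiked_tissue"] != "")]
        return dict(zip(sub["probeset"], sub["spiked_tissue"]))


@dataclass
class SyntheticDataset:
    """Everything :func:`simulate_dataset` produces, in memory."""

    config: SimulationConfig
    matrices: dict[tuple[str, str], ExpressionMatrix]  # (species, protocol) -> raw matrix
    exon_sequences: dict[str, dict[str, str]]  # species -> probeset -> sequence
    refseq_db: dict[str, str]
    est_db: dict[str, str]
    homology: pd.DataFrame  # group_id, species, gene_id
    transcripts: dict[str, pd.DataFrame]  # species -> BED6-like frame
    probeset_intervals: dict[str, pd.DataFrame]  # species -> name/chrom/start/end/strand
    gene_annotation: dict[str, dict[str, list[str]]]  # species -> gene_id -> probesets
    truth: SyntheticTruth


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site always changes to one of the three other bases
    (uniformly), so ``rate=1`` retains no original base.  Length is
    preserved; indels are not modeled.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    if not np.isin(arr, _BASES).all():
        raise ValueError("sequence contains non-ACGT characters")
    hit = rng.random(arr.size) < rate
    if hit.any():
        # index of current base 0..3; shift by 1..3 to guarantee a change
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_profile_pair(
    base: np.ndarray,
    alpha: float,
    noise_sd: float,
    rng: np.random.Generator,
    mean: float = 8.0,
    latent_sd: float = 1.0,
    clip: tuple[float, float] = (0.5, 15.5),
) -> tuple[np.ndarray, np.ndarray]:
    """One cross-species profile pair from a shared latent deviation vector."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    b = np.asarray(base, dtype=float)
    out = []
    for _ in range(2):
        indep = rng.normal(0.0, latent_sd, size=b.shape)
        noise = rng.normal(0.0, noise_sd, size=b.shape) if noise_sd > 0 else 0.0
        out.append(np.clip(mean + alpha * b + (1.0 - alpha) * indep + noise, *clip))
    return out[0], out[1]


def simulate_profile_pairs(
    n_pairs: int,
    n_tissues: int,
    alpha: float,
    noise_sd: float,
    rng: np.random.Generator,
    mean: float = 8.0,
    latent_sd: float = 1.0,
    clip: tuple[float, float] = (0.5, 15.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`simulate_profile_pair`: two ``(n_pairs, T)`` arrays."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    shape = (n_pairs, n_tissues)
    b = rng.normal(0.0, latent_sd, size=shape)
    out = []
    for _ in range(2):
        indep = rng.normal(0.0, latent_sd, size=shape)
        noise = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else 0.0
        out.append(np.clip(mean + alpha * b + (1.0 - alpha) * indep + noise, *clip))
    return out[0], out[1]


def simulate_tissue_panel(
    n_background: int,
    n_spiked: int,
    rng: np.random.Generator,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    background_mean: float = 6.0,
    background_sd: float = 0.2,
    spike_magnitude: float = 3.0,
    species: str = "mouse",
    protocol: str = "antisense",
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """A single averaged matrix of flat-background probesets plus spike-ins.

    Background probesets fluctuate around a sub-threshold baseline; spiked
    probesets additionally carry ``spike_magnitude`` in one random tissue.
    Returns the matrix and the truth map probeset → spiked tissue.
    """
    T = len(tissues)
    n = n_background + n_spiked
    X = rng.normal(background_mean, background_sd, size=(n, T))
    spike_idx = rng.integers(0, T, size=n_spiked)
    X[np.arange(n_spiked), spike_idx] += spike_magnitude
    ids = [f"{species}_tsx{i:05d}" for i in range(n)]
    truth = {ids[i]: tissues[spike_idx[i]] for i in range(n_spiked)}
    data = pd.DataFrame(X, index=pd.Index(ids, name="probeset_id"), columns=list(tissues))
    return ExpressionMatrix(species=species, protocol=protocol, data=data), truth


def _alpha_sd(alpha: np.ndarray, latent_sd: float, noise_sd: float) -> np.ndarray:
    """Theoretical sd of a deviation under the mixture model."""
    return np.sqrt((alpha**2 + (1.0 - alpha) ** 2) * latent_sd**2 + noise_sd**2)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full multi-species, dual-protocol dataset.

    Deterministic under a fixed ``config.seed``; independent child RNG
    streams are derived for sequences, expression, spike placement and
    novelty so the stages are individually reproducible.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_expr, rng_spike, rng_novel, rng_extra = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    species = list(cfg.species)
    S, G, U = len(species), cfg.n_ortholog_groups, cfg.n_unpaired_probesets
    tissues = list(cfg.tissues)
    T = len(tissues)
    lo, hi = cfg.intensity_range

    # ---- per-locus conservation weights, shared across strands ------------
    eta = rng_expr.normal(0.0, 1.0, size=G)
    alpha_s = np.clip(cfg.alpha_sense + cfg.alpha_jitter * eta, 0.0, 1.0)
    alpha_a = np.clip(cfg.alpha_antisense + cfg.alpha_jitter * eta, 0.0, 1.0)

    # ---- expression: ortholog groups --------------------------------------
    def group_deviations(alpha: np.ndarray) -> np.ndarray:
        b = rng_expr.normal(0.0, cfg.latent_sd, size=(G, T))
        u = rng_expr.normal(0.0, cfg.latent_sd, size=(S, G, T))
        eps = rng_expr.normal(0.0, cfg.noise_sd, size=(S, G, T))
        a = alpha[None, :, None]
        return a * b[None, :, :] + (1.0 - a) * u + eps

    dev_sense = group_deviations(alpha_s)
    dev_anti_own = group_deviations(alpha_a)
    sd_s = _alpha_sd(alpha_s, cfg.latent_sd, cfg.noise_sd)[None, :, None]
    sd_a = _alpha_sd(alpha_a, cfg.latent_sd, cfg.noise_sd)[None, :, None]
    rho = cfg.sense_antisense_rho
    dev_anti = rho * (dev_sense / sd_s) * sd_a + np.sqrt(1.0 - rho**2) * dev_anti_own

    mu_s, mu_a = cfg.expressed_mean, cfg.expressed_mean + cfg.antisense_offset
    vals = {
        "sense": np.clip(mu_s + dev_sense, lo, hi),  # (S, G, T)
        "antisense": np.clip(mu_a + dev_anti, lo, hi),
    }

    # ---- expression: unpaired probesets (background + spike-ins) ----------
    n_spiked = int(round(cfg.frac_tissue_specific * U))
    spike_tissue_idx = rng_spike.integers(0, T, size=(S, n_spiked))
    unpaired = {}
    for prot in ("sense", "antisense"):
        Xu = rng_expr.normal(cfg.background_mean, cfg.background_sd, size=(S, U, T))
        for s in range(S):
            Xu[s, np.arange(n_spiked), spike_tissue_idx[s]] += cfg.spike_magnitude
        unpaired[prot] = np.clip(Xu, lo, hi)

    # ---- assemble matrices with replicates and optional extra tissues -----
    matrices: dict[tuple[str, str], ExpressionMatrix] = {}
    probeset_ids = {
        sp: [f"{sp}_ps{i:05d}" for i in range(G + U)] for sp in species
    }
    all_tissues = tissues + list(cfg.extra_tissues)
    for prot in ("sense", "antisense"):
        for s, sp in enumerate(species):
            core = np.concatenate([vals[prot][s], unpaired[prot][s]], axis=0)  # (G+U, T)
            if cfg.extra_tissues:
                extra = np.clip(
                    rng_extra.normal(
                        cfg.expressed_mean + 1.0, 1.0, size=(G + U, len(cfg.extra_tissues))
                    ),
                    lo, hi,
                )
                core = np.concatenate([core, extra], axis=1)
            reps = core[:, :, None] + rng_expr.normal(
                0.0, cfg.replicate_sd, size=(G + U, len(all_tissues), cfg.n_replicates)
            )
            reps = np.clip(reps, lo, hi)
            cols = [f"{t}_rep{k + 1}" for t in all_tissues for k in range(cfg.n_replicates)]
            flat = reps.reshape(G + U, len(all_tissues) * cfg.n_replicates)
            data = pd.DataFrame(
                flat, index=pd.Index(probeset_ids[sp], name="probeset_id"), columns=cols
            )
            matrices[(sp, prot)] = ExpressionMatrix(species=sp, protocol=prot, data=data)

    # ---- sequences: ancestors, species exons, decoys -----------------------
    exon_sequences: dict[str, dict[str, str]] = {sp: {} for sp in species}
    for g in range(G):
        ancestor = random_sequence(cfg.seq_length, rng_seq)
        for sp in species:
            exon_sequences[sp][probeset_ids[sp][g]] = mutate_sequence(
                ancestor, cfg.substitution_rate, rng_seq
            )
    for sp in species:
        for i in range(G, G + U):
            exon_sequences[sp][probeset_ids[sp][i]] = random_sequence(cfg.seq_length, rng_seq)

    # ---- homology table and gene annotation --------------------------------
    hom_rows = []
    gene_annotation: dict[str, dict[str, list[str]]] = {sp: {} for sp in species}
    for g in range(G):
        gid = f"OG{g:05d}"
        for sp in species:
            gene = f"{sp}_g{g:05d}"
            hom_rows.append((gid, sp, gene))
            gene_annotation[sp][gene] = [probeset_ids[sp][g]]
    homology = pd.DataFrame(hom_rows, columns=["group_id", "species", "gene_id"])

    # ---- genomic intervals and transcript annotation -----------------------
    transcripts: dict[str, pd.DataFrame] = {}
    probeset_intervals: dict[str, pd.DataFrame] = {}
    dual_flags: dict[str, np.ndarray] = {}
    for sp in species:
        n_ps = G + U
        starts = np.arange(n_ps) * (cfg.seq_length + 850)
        ends = starts + cfg.seq_length
        probeset_intervals[sp] = pd.DataFrame(
            {
                "name": probeset_ids[sp],
                "chrom": "chr1",
                "start": starts,
                "end": ends,
                "strand": "+",
            }
        )
        dual = rng_novel.random(n_ps) < cfg.frac_dual_overlap
        dual_flags[sp] = dual
        rows = []
        for i in range(n_ps):
            rows.append(
                ("chr1", int(starts[i] - 50), int(ends[i] + 50), f"{sp}_tx{i:05d}", 0, "+")
            )
            if dual[i]:
                rows.append(
                    ("chr1", int(starts[i] - 10), int(ends[i] + 10), f"{sp}_txm{i:05d}", 0, "-")
                )
        transcripts[sp] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    # ---- reference databases and novelty truth -----------------------------
    from Bio.Seq import reverse_complement

    refseq_db: dict[str, str] = {}
    est_db: dict[str, str] = {}
    novel_flags: dict[str, np.ndarray] = {}
    rec = 0
    for sp in species:
        novel = rng_novel.random(G + U) < cfg.frac_novel
        novel_flags[sp] = novel
        for i, pid in enumerate(probeset_ids[sp]):
            if novel[i]:
                continue
            embedded = (
                random_sequence(int(rng_novel.integers(10, 60)), rng_novel)
                + reverse_complement(exon_sequences[sp][pid])
                + random_sequence(int(rng_novel.integers(10, 60)), rng_novel)
            )
            choice = int(rng_novel.integers(0, 3))  # 0: refseq, 1: est, 2: both
            if choice in (0, 2):
                refseq_db[f"REF{rec:06d}"] = embedded
            if choice in (1, 2):
                est_db[f"EST{rec:06d}"] = embedded
            rec += 1
    # filler records so the databases are not pure embeddings
    for j in range(20):
        refseq_db[f"REFX{j:04d}"] = random_sequence(300, rng_novel)
        est_db[f"ESTX{j:04d}"] = random_sequence(300, rng_novel)

    # ---- truth tables -------------------------------------------------------
    truth_rows = []
    for s, sp in enumerate(species):
        spiked = {probeset_ids[sp][G + j]: tissues[spike_tissue_idx[s, j]] for j in range(n_spiked)}
        for i, pid in enumerate(probeset_ids[sp]):
            truth_rows.append(
                (
                    sp,
                    pid,
                    f"OG{i:05d}" if i < G else "",
                    spiked.get(pid, ""),
                    bool(novel_flags[sp][i]),
                    bool(dual_flags[sp][i]),
                )
            )
    truth_probesets = pd.DataFrame(
        truth_rows,
        columns=["species", "probeset", "group_id", "spiked_tissue", "novel", "dual_overlap"],
    )
    truth_groups = pd.DataFrame(
        {
            "group_id": [f"OG{g:05d}" for g in range(G)],
            "alpha_sense": alpha_s,
            "alpha_antisense": alpha_a,
        }
    )

    return SyntheticDataset(
        config=cfg,
        matrices=matrices,
        exon_sequences=exon_sequences,
        refseq_db=refseq_db,
        est_db=est_db,
        homology=homology,
        transcripts=transcripts,
        probeset_intervals=probeset_intervals,
        gene_annotation=gene_annotation,
        truth=SyntheticTruth(probesets=truth_probesets, groups=truth_groups),
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every generated artifact to ``outdir`` in the pipeline's formats.

    File layout matches what :class:`natcons.pipeline.PipelineConfig`
    expects: per species×protocol expression TSVs, per-species exon FASTA
    and BED files, the homology TSV, the two reference FASTA databases, the
    truth tables and the config as YAML.  Output is deterministic for a
    fixed dataset.
    """
    from pathlib import Path

    from .io import (
        write_bed,
        write_expression_table,
        write_fasta,
        write_homology,
        write_yaml,
    )

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (sp, prot), matrix in sorted(dataset.matrices.items()):
        write_expression_table(matrix, out / f"{sp}_{prot}_expression.tsv")
    for sp, seqs in sorted(dataset.exon_sequences.items()):
        write_fasta(seqs, out / f"{sp}_exons.fasta")
    write_fasta(dataset.refseq_db, out / "refseq_standin.fasta")
    write_fasta(dataset.est_db, out / "est_standin.fasta")
    write_homology(dataset.homology, out / "homology.tsv")
    for sp, bed in sorted(dataset.transcripts.items()):
        write_bed(bed, out / f"{sp}_transcripts.bed")
    for sp, iv in sorted(dataset.probeset_intervals.items()):
        bed6 = iv.assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]]
        write_bed(bed6, out / f"{sp}_probesets.bed")
    dataset.truth.probesets.sort_values(["species", "probeset"]).to_csv(
        out / "truth_probesets.tsv", sep="\t", index=False
    )
    dataset.truth.groups.to_csv(out / "truth_groups.tsv", sep="\t", index=False)
    write_yaml(dataset.config.to_dict(), out / "config.yaml")
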
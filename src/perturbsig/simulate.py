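"""Synthetic L1000-like signature generator.

Emulates the statistical structure of large-scale RNAi / CRISPR
perturbational datasets in landmark space: reagents targeting the same
gene share an on-target expression pattern; shRNAs sharing a miRNA-like
seed share a (typically stronger) off-target pattern; every signature
carries a component along one global "generic response" axis (the
empirical PC1); landmark target transcripts are directly depressed by
knockdown; and each reagent is profiled in replicate with i.i.d. noise.

Replicate ``r`` of reagent ``j`` (gene ``g``, seed ``s``, cell line ``c``)
is generated as::

    x = alpha_j * u_g + beta_{s,c} * v_s + gamma_j * w + noise - delta * e_g

with ``u_g``, ``v_s``, ``w`` i.i.d. unit Gaussian directions, noise i.i.d.
N(0, sigma_noise^2) per gene, and ``e_g`` the indicator of the target
landmark.  sgRNA reagents carry no seed term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .core import SignatureMatrix
from .errors import InvalidConfigError

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SENSE_LENGTH = 21
#: 1-based start of the seed heptamer on the sense strand (main Dicer product)
SEED_START = 11


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic generator.

    Magnitudes are in z-score units.  With the defaults the on-target,
    seed, and generic components are roughly 20%, 30%, and 20% of a
    signature's length, and the seed effect dominates the gene effect for
    shRNAs; sgRNA datasets carry no seed term at all.
    """

    n_genes_targeted: int = 50
    reagents_per_gene: int = 6
    n_seed_pool: int = 40
    n_cell_lines: int = 3
    n_landmarks: int = 978
    replicates: int = 3
    alpha_on: float = 6.5
    beta_seed: float = 10.0
    gamma_pc1: float = 10.0
    sigma_noise: float = 1.0
    delta_knockdown: float = 4.0
    pert_type: str = "shRNA"
    #: fraction of seeds whose effect magnitude is near-constant across cell lines
    seed_consistent_fraction: float = 0.7
    #: fraction of shRNAs whose effective seed is Dicer-shifted to position 12
    dicer_shift_fraction: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_on", "beta_seed", "gamma_pc1", "sigma_noise",
                     "delta_knockdown"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.reagents_per_gene < 1:
            raise InvalidConfigError("reagents_per_gene must be >= 1")
        if self.n_seed_pool < 1:
            raise InvalidConfigError("n_seed_pool must be >= 1")
        if self.pert_type not in ("shRNA", "sgRNA"):
            raise InvalidConfigError("pert_type must be shRNA or sgRNA")
        if self.n_genes_targeted > self.n_landmarks:
            raise InvalidConfigError("more targeted genes than landmarks")
        if not 0 <= self.seed_consistent_fraction <= 1:
            raise InvalidConfigError("seed_consistent_fraction must be in [0,1]")
        if not 0 <= self.dicer_shift_fraction <= 1:
            raise InvalidConfigError("dicer_shift_fraction must be in [0,1]")

    @classmethod
    def sgrna(cls, **kwargs) -> "GeneratorConfig":
        """Default CRISPR configuration: same on-target and generic structure
        as the shRNA default but no seed-driven off-target term."""
        kwargs.setdefault("pert_type", "sgRNA")
        kwargs.setdefault("beta_seed", 0.0)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Generating parameters stored alongside every synthetic dataset.

    Unit-norm patterns: ``u`` (landmarks x genes), ``v`` (landmarks x
    seeds), ``w`` (the generic axis).  Per-reagent magnitudes ``alpha`` and
    ``gamma``; per-(seed, cell line) magnitudes ``beta``.
    """

    gene_ids: list = field(default_factory=list)
    cell_lines: list = field(default_factory=list)
    seed_pool: list = field(default_factory=list)
    reagent_ids: list = field(default_factory=list)
    u: np.ndarray = None
    v: np.ndarray = None
    w: np.ndarray = None
    alpha: np.ndarray = None
    gamma: np.ndarray = None
    beta: np.ndarray = None
    reagent_gene_index: np.ndarray = None
    reagent_seed_index: np.ndarray = None
    seed_consistent: np.ndarray = None
    dicer_shifted: np.ndarray = None

    def to_json(self, path) -> None:
        payload = {}
        for key, val in asdict(self).items():
            payload[key] = val.tolist() if isinstance(val, np.ndarray) else val
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        for key in ("u", "v", "w", "alpha", "gamma", "beta"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=float)
        for key in ("reagent_gene_index", "reagent_seed_index"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=int)
        for key in ("seed_consistent", "dicer_shifted"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=bool)
        return cls(**payload)


def landmark_ids(n: int) -> list[str]:
    """Zero-padded landmark gene ids; lexicographic order == numeric order."""
    return [f"L{i:04d}" for i in range(1, n + 1)]


#: skewed base composition for seed heptamers.  A small pool of uniform
#: random 7-mers almost never shares subwords across distinct seeds, which
#: a real seed population (thousands of heptamers) does constantly; the
#: skew restores realistic subword-collision rates, so that sense-strand
#: windows partially overlapping the seed region group mostly
#: different-seed (uncorrelated) pairs, as in real window scans.
_SEED_BASE_PROBS = np.array([0.75, 0.1, 0.1, 0.05])


def _random_seed_pool(n: int, rng: np.random.Generator) -> list[str]:
    """Draw n distinct seed heptamers with skewed base composition."""
    total = 4 ** 7
    if n > total:
        raise InvalidConfigError(f"cannot draw {n} distinct heptamers")
    digits = (np.arange(total)[:, None] // 4 ** np.arange(6, -1, -1)) % 4
    probs = _SEED_BASE_PROBS[digits].prod(axis=1)
    chosen = rng.choice(total, size=n, replace=False, p=probs / probs.sum())
    return ["".join(_BASES[d] for d in digits[c]) for c in chosen]


def generate_reagent_table(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    seed_pool: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw the reagent annotation table.

    Each shRNA gets a random 21-nt sense strand whose seed window carries
    the reverse complement of a heptamer drawn from a shared pool, so that
    reagents targeting different genes collide on seeds at a rate set by
    ``n_seed_pool``.  A ``dicer_shift_fraction`` of shRNAs have the seed
    written one position downstream (start 12 instead of 11), mimicking
    heterogeneous Dicer processing; the recorded seed6/seed7 is the
    effective (drawn) seed in both cases.  sgRNA reagents get the same
    sequence/seed annotation (an sgRNA's "seed" has no biological role;
    the annotation provides the null contrast in which same-seed pairs
    behave like random pairs because the seed effect magnitude is 0).

    Returns the table (indexed by reagent_id) and a dict of draw indices
    used by :func:`generate_signature_dataset`.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if seed_pool is None:
        seed_pool = _random_seed_pool(config.n_seed_pool, rng)
    genes = landmark_ids(config.n_landmarks)[: config.n_genes_targeted]
    rows = []
    seed_idx_list = []
    gene_idx_list = []
    shifted_list = []
    for gi, gene in enumerate(genes):
        for k in range(config.reagents_per_gene):
            rid = f"{config.pert_type}_{gene}_{k + 1:02d}"
            s_idx = int(rng.integers(config.n_seed_pool))
            seed7 = seed_pool[s_idx]
            shifted = bool(rng.random() < config.dicer_shift_fraction)
            start = SEED_START + (1 if shifted else 0)  # 1-based
            sense = rng.choice(_BASES, size=SENSE_LENGTH)
            sense[start - 1: start + 6] = list(reverse_complement(seed7))
            rows.append(
                dict(reagent_id=rid, pert_type=config.pert_type,
                     target_gene=gene, seed6=seed7[:6], seed7=seed7,
                     sense_sequence="".join(sense))
            )
            seed_idx_list.append(s_idx)
            gene_idx_list.append(gi)
            shifted_list.append(shifted)
    table = pd.DataFrame(rows).set_index("reagent_id")
    draws = {
        "seed_pool": seed_pool,
        "gene_index": np.array(gene_idx_list),
        "seed_index": np.array(seed_idx_list),
        "shifted": np.array(shifted_list, dtype=bool),
        "genes": genes,
    }
    return table, draws


def _seed_patterns(seed_pool: list[str], unit_columns) -> np.ndarray:
    """One off-target pattern per distinct 6-mer seed (nts 1-6 of the
    7-mer): the hexamer is the core determinant of miRNA-like targeting,
    so pool seeds sharing it share their off-target expression pattern."""
    classes: dict[str, int] = {}
    for s in seed_pool:
        classes.setdefault(s[:6], len(classes))
    v6 = unit_columns(len(classes))
    return v6[:, [classes[s[:6]] for s in seed_pool]]


def generate_signature_dataset(
    config: GeneratorConfig,
    patterns: Optional[GroundTruth] = None,
) -> tuple[SignatureMatrix, GroundTruth]:
    """Generate a replicate-level synthetic dataset plus its ground truth.

    Fully reproducible from ``config.rng_seed``.  Passing the
    :class:`GroundTruth` of a previous run as ``patterns`` reuses its
    generating directions (``u``, ``v``, ``w``) so that, e.g., an sgRNA
    dataset shares gene patterns and the generic axis with an shRNA one.
    """
    rng = np.random.default_rng(config.rng_seed)
    table, draws = generate_reagent_table(config, rng)
    n_reagents = len(table)
    genes_all = landmark_ids(config.n_landmarks)
    cell_lines = [f"CL{c + 1}" for c in range(config.n_cell_lines)]

    def unit_columns(k: int) -> np.ndarray:
        mat = rng.standard_normal((config.n_landmarks, k))
        return mat / np.linalg.norm(mat, axis=0, keepdims=True)

    if patterns is not None:
        if (patterns.u.shape != (config.n_landmarks, config.n_genes_targeted)
                or patterns.w.shape != (config.n_landmarks,)):
            raise InvalidConfigError(
                "shared patterns do not match this configuration's dimensions"
            )
        u, w = patterns.u.copy(), patterns.w.copy()
        v = (patterns.v.copy()
             if patterns.v.shape == (config.n_landmarks, config.n_seed_pool)
             else unit_columns(config.n_seed_pool))
    else:
        u = unit_columns(config.n_genes_targeted)
        v = _seed_patterns(draws["seed_pool"], unit_columns)
        w = unit_columns(1)[:, 0]

    alpha = config.alpha_on * rng.uniform(0.5, 1.5, size=n_reagents)
    # exponential magnitudes give the generic axis the large across-signature
    # variance that makes it the empirical PC1 (its hallmark in real data)
    gamma = config.gamma_pc1 * rng.exponential(1.0, size=n_reagents)

    seed_consistent = rng.random(config.n_seed_pool) < config.seed_consistent_fraction
    base_beta = config.beta_seed * rng.uniform(0.5, 1.5, size=config.n_seed_pool)
    beta = np.empty((config.n_seed_pool, config.n_cell_lines))
    for s in range(config.n_seed_pool):
        if seed_consistent[s]:
            beta[s, :] = base_beta[s]
        else:
            beta[s, :] = config.beta_seed * rng.uniform(
                0.1, 1.9, size=config.n_cell_lines
            )

    gene_idx = draws["gene_index"]
    seed_idx = draws["seed_index"]
    n_sigs = n_reagents * config.n_cell_lines * config.replicates
    data = np.empty((config.n_landmarks, n_sigs))
    sig_ids: list[str] = []
    meta_rows: list[dict] = []
    col = 0
    for j, rid in enumerate(table.index):
        base_signal = alpha[j] * u[:, gene_idx[j]] + gamma[j] * w
        seed_part = v[:, seed_idx[j]]
        for c, cell in enumerate(cell_lines):
            signal = base_signal + beta[seed_idx[j], c] * seed_part
            signal[gene_idx[j]] -= config.delta_knockdown
            for r in range(config.replicates):
                noise = rng.standard_normal(config.n_landmarks) * config.sigma_noise
                data[:, col] = signal + noise
                sig_id = f"{rid}:{cell}:r{r + 1}"
                sig_ids.append(sig_id)
                row = table.loc[rid].to_dict()
                row.update(
                    sig_id=sig_id,
                    reagent_id=rid,
                    cell_line=cell,
                    replicate_group=f"{rid}:{cell}",
                )
                meta_rows.append(row)
                col += 1

    frame = pd.DataFrame(data, index=genes_all, columns=sig_ids)
    meta = pd.DataFrame(meta_rows).set_index("sig_id")
    truth = GroundTruth(
        gene_ids=draws["genes"],
        cell_lines=cell_lines,
        seed_pool=draws["seed_pool"],
        reagent_ids=list(table.index),
        u=u,
        v=v,
        w=w,
        alpha=alpha,
        gamma=gamma,
        beta=beta,
        reagent_gene_index=gene_idx,
        reagent_seed_index=seed_idx,
        seed_consistent=seed_consistent,
        dicer_shifted=draws["shifted"],
    )
    return SignatureMatrix(frame, meta), truth
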
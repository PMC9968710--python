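"""Synthetic multi-tissue methylation cohorts with known ground truth.

The generator plants, in disjoint probe sets: cross-tissue correlated
inter-individual signal, genotype-driven 2-/3-cluster probes, cell-composition
confounded probes, and near-constant ("flat") probes, on top of a bimodal
per-tissue baseline.  A single integer seed governs all randomness through
deterministic per-stage substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .types import (
    BLOOD_CELL_TYPES,
    BRAIN_CELL_TYPES,
    EPITHELIAL_CELL_TYPES,
    MultiTissueDataset,
    TISSUES,
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    n_subjects: int = 19
    n_probes: int = 10_000
    tissues: Tuple[str, ...] = TISSUES
    frac_correlated: float = 0.0
    rho_true: float = 0.7
    frac_snp2: float = 0.0
    frac_snp3: float = 0.0
    allele_freq: float = 0.3
    noise_sd: float = 0.02
    frac_detection_fail: float = 0.0
    seed: int = 0
    # secondary knobs -----------------------------------------------------
    frac_cell_confounded: float = 0.0
    frac_flat: float = 0.0
    latent_sd: float = 0.5           # logit-scale inter-individual spread
    cell_effect: float = 2.0         # logit-scale slope on the primary cell type
    snp_noise_sd: float = 0.02       # within-genotype-cluster beta noise
    tissue_flip_fracs: Dict[str, float] = field(default_factory=lambda: {
        "brain": 0.12, "blood": 0.05, "saliva": 0.045, "buccal": 0.06,
    })

    def __post_init__(self) -> None:
        planted = (self.frac_correlated + self.frac_snp2 + self.frac_snp3
                   + self.frac_cell_confounded + self.frac_flat)
        if planted > 1.0 + 1e-12:
            raise ConfigurationError(
                f"planted probe fractions sum to {planted:.3f} > 1")
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        if not -1.0 <= self.rho_true <= 1.0:
            raise ConfigurationError("rho_true must lie in [-1, 1]")
        if not 0.0 < self.allele_freq < 1.0:
            raise ConfigurationError("allele_freq must lie in (0, 1)")
        if not 0.0 <= self.frac_detection_fail <= 1.0:
            raise ConfigurationError("frac_detection_fail must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(self.tissues) < 2:
            raise ConfigurationError("need at least two tissues")
        if abs(self.rho_true) > 0 and self.frac_correlated > 0:
            # a planted rho is unattainable if measurement noise swamps the
            # inter-individual latent spread entirely
            if self.latent_sd <= 0:
                raise ConfigurationError(
                    "rho_true unattainable with latent_sd <= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated cohort."""

    correlated_probes: Dict[str, float] = field(default_factory=dict)
    snp_probes: Dict[str, dict] = field(default_factory=dict)
    variable_probes_expected: Set[str] = field(default_factory=set)
    cell_proportions_true: Dict[str, pd.DataFrame] = field(default_factory=dict)
    cell_confounded_probes: Set[str] = field(default_factory=set)
    flat_probes: Set[str] = field(default_factory=set)
    detection_bad_probes: Dict[str, List[str]] = field(default_factory=dict)
    detection_bad_samples: Dict[str, List[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flatten per-probe truth into one row per probe."""
        rows = []
        for pid, rho in self.correlated_probes.items():
            rows.append((pid, "correlated", rho, np.nan))
        for pid, info in self.snp_probes.items():
            rows.append((pid, "snp", np.nan, info["k"]))
        for pid in sorted(self.cell_confounded_probes):
            rows.append((pid, "cell_confounded", np.nan, np.nan))
        for pid in sorted(self.flat_probes):
            rows.append((pid, "flat", np.nan, np.nan))
        return pd.DataFrame(rows, columns=["probe_id", "role", "rho_true", "snp_k"])


def _probe_ids(n: int) -> List[str]:
    width = max(6, len(str(n)))
    return [f"cg{i:0{width}d}" for i in range(n)]


def _subject_ids(n: int) -> List[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _draw_cell_proportions(config: SimulationConfig) -> Dict[str, pd.DataFrame]:
    rng = _substream(config.seed, 10)
    subjects = _subject_ids(config.n_subjects)
    props: Dict[str, pd.DataFrame] = {}
    for tissue in config.tissues:
        if tissue == "brain":
            neuron = rng.beta(8, 12, size=config.n_subjects)  # mean 0.4
            table = pd.DataFrame(
                {"neuron": neuron, "non_neuron": 1 - neuron}, index=subjects)
        elif tissue == "blood":
            alpha = np.array([1.5, 1.0, 3.0, 2.0, 1.5, 11.0])
            table = pd.DataFrame(
                rng.dirichlet(alpha, size=config.n_subjects),
                index=subjects, columns=list(BLOOD_CELL_TYPES))
        else:  # saliva / buccal
            mean = 0.6 if tissue == "saliva" else 0.85
            a = mean * 20
            epi = rng.beta(a, 20 - a, size=config.n_subjects)
            table = pd.DataFrame(
                {"epithelial": epi, "immune": 1 - epi}, index=subjects)
        table.index.name = "subject_id"
        props[tissue] = table
    return props


_PRIMARY_CELL = {"brain": "neuron", "blood": "CD4T",
                 "saliva": "epithelial", "buccal": "epithelial"}


def _assign_roles(config: SimulationConfig,
                  rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Disjoint probe-index sets per planted role."""
    n = config.n_probes
    counts = {
        "correlated": int(round(config.frac_correlated * n)),
        "snp2": int(round(config.frac_snp2 * n)),
        "snp3": int(round(config.frac_snp3 * n)),
        "cell": int(round(config.frac_cell_confounded * n)),
        "flat": int(round(config.frac_flat * n)),
    }
    if sum(counts.values()) > n:
        raise ConfigurationError("planted probe counts exceed n_probes")
    perm = rng.permutation(n)
    roles, start = {}, 0
    for name, cnt in counts.items():
        roles[name] = np.sort(perm[start:start + cnt])
        start += cnt
    return roles


def generate_cohort(config: SimulationConfig) -> Tuple[MultiTissueDataset, SyntheticTruth]:
    """Generate one beta matrix per tissue plus the ground truth.

    Baselines are a two-component Beta mixture shared across tissues with
    tissue-specific mode flips and logit jitter, so tissues separate on MDS
    while per-probe means stay highly correlated.  Cross-tissue correlated
    probes share a per-subject latent factor on the logit scale with loading
    sqrt(|rho_true|); independent tissue noise carries the remaining
    variance, so the latent cross-tissue correlation is exactly rho_true.
    """
    tissues = list(config.tissues)
    probes = _probe_ids(config.n_probes)
    subjects = _subject_ids(config.n_subjects)
    n, m = config.n_probes, config.n_subjects

    rng_roles = _substream(config.seed, 0)
    rng_base = _substream(config.seed, 1)
    rng_latent = _substream(config.seed, 2)
    rng_noise = _substream(config.seed, 3)
    rng_geno = _substream(config.seed, 4)

    roles = _assign_roles(config, rng_roles)

    # --- baseline: global bimodal mixture + per-tissue flips/jitter --------
    hyper = rng_base.random(n) < 0.5
    base = np.where(hyper, rng_base.beta(18, 2, size=n), rng_base.beta(2, 18, size=n))
    base = np.clip(base, 1e-4, 1 - 1e-4)
    base_logit = logit(base)

    tissue_logits: Dict[str, np.ndarray] = {}
    for tissue in tissues:
        flip_frac = config.tissue_flip_fracs.get(tissue, 0.05)
        flips = rng_base.random(n) < flip_frac
        jitter = rng_base.normal(0.0, 0.3, size=n)
        tl = np.where(flips, -base_logit, base_logit) + jitter
        tissue_logits[tissue] = tl

    # --- inter-individual deviations on the logit scale --------------------
    sd = np.full(n, config.latent_sd)
    sd[roles["flat"]] = 0.0
    rho = config.rho_true
    a = np.sqrt(abs(rho))
    shared = rng_latent.standard_normal((n, m))           # per-subject factor
    is_corr = np.zeros(n, dtype=bool)
    is_corr[roles["correlated"]] = True

    props = _draw_cell_proportions(config)

    betas: Dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        own = rng_latent.standard_normal((n, m))
        dev = np.where(is_corr[:, None],
                       a * shared + np.sqrt(max(0.0, 1 - abs(rho))) * own,
                       own)
        if rho < 0 and tissue == "brain":
            # negative planted rho: brain loads on the shared factor with
            # opposite sign to every peripheral tissue
            dev = np.where(is_corr[:, None],
                           -a * shared + np.sqrt(1 - abs(rho)) * own, dev)
        logits = tissue_logits[tissue][:, None] + sd[:, None] * dev

        if roles["cell"].size and tissue in _PRIMARY_CELL:
            cell = _PRIMARY_CELL[tissue]
            if cell in props[tissue].columns:
                p = props[tissue][cell].to_numpy()
                centered = p - p.mean()
                logits[roles["cell"], :] += config.cell_effect * centered[None, :]

        beta = expit(logits)
        if config.noise_sd > 0:
            beta = beta + rng_noise.normal(0.0, config.noise_sd, size=beta.shape)
        beta = np.clip(beta, 0.0, 1.0)
        betas[tissue] = pd.DataFrame(beta, index=probes, columns=subjects)

    truth = SyntheticTruth(
        correlated_probes={probes[i]: rho for i in roles["correlated"]},
        cell_confounded_probes={probes[i] for i in roles["cell"]},
        flat_probes={probes[i] for i in roles["flat"]},
        cell_proportions_true={t: p.copy() for t, p in props.items()},
    )

    dataset = MultiTissueDataset(betas=betas,
                                 cell_proportions={t: p.copy() for t, p in props.items()})

    # --- genotype-driven multimodal probes ---------------------------------
    snp_ids = {}
    for k, key in ((2, "snp2"), (3, "snp3")):
        for i in roles[key]:
            snp_ids[probes[i]] = k
    if snp_ids:
        dataset = inject_snp_probes(dataset, truth, config, snp_ids, rng=rng_geno)

    truth.variable_probes_expected = _expected_variable(config, tissues, tissue_logits,
                                                        sd, roles, probes)
    return dataset, truth


def _expected_variable(config, tissues, tissue_logits, sd, roles, probes) -> Set[str]:
    """Probes expected to pass the trimmed-range rule in every tissue.

    Uses the noiseless construction: the trimmed (10th-90th pctile) range of
    expit(mu + sd*Z) is approximately expit(mu + 1.28*sd) - expit(mu - 1.28*sd).
    Probes are expected-variable when that analytic range clears 1.5x the
    0.05 threshold in every tissue (margin keeps the prediction robust to
    sampling noise); SNP probes are excluded (their values are overwritten).
    """
    z = 1.2816  # 10th/90th percentile of the standard normal
    expected = np.ones(config.n_probes, dtype=bool)
    for tissue in tissues:
        mu = tissue_logits[tissue]
        rng_span = expit(mu + z * sd) - expit(mu - z * sd)
        expected &= rng_span >= 0.075
    for key in ("snp2", "snp3"):
        expected[roles[key]] = False
    return {probes[i] for i in np.flatnonzero(expected)}


# genotype value -> cluster center, additive coding
_K3_CENTERS = np.array([0.05, 0.5, 0.95])


def inject_snp_probes(dataset: MultiTissueDataset,
                      truth: SyntheticTruth,
                      config: SimulationConfig,
                      probe_k: Optional[Dict[str, int]] = None,
                      rng: Optional[np.random.Generator] = None) -> MultiTissueDataset:
    """Overwrite designated probes with genotype-driven cluster structure.

    Genotypes are drawn once per subject (Hardy-Weinberg: Binomial(2,
    allele_freq) copies of the B allele) and shared across tissues.  k=3 maps
    additively onto centers (0.05, 0.5, 0.95); k=2 collapses dominantly
    (carriers of B vs. non-carriers -> 0.95 vs 0.05).
    """
    if rng is None:
        rng = _substream(config.seed, 4)
    if probe_k is None:
        probe_k = {pid: info["k"] for pid, info in truth.snp_probes.items()}
    subjects = dataset.subjects
    m = len(subjects)
    for pid, k in probe_k.items():
        if pid in truth.correlated_probes:
            raise ConfigurationError(
                f"probe {pid} already carries planted correlated signal")
        geno = rng.binomial(2, config.allele_freq, size=m)
        if k == 3:
            centers = _K3_CENTERS[geno]
        elif k == 2:
            centers = np.where(geno > 0, 0.95, 0.05)
        else:
            raise ConfigurationError(f"unsupported cluster count k={k}")
        for tissue in dataset.tissues:
            vals = centers + rng.normal(0.0, config.snp_noise_sd, size=m)
            dataset.betas[tissue].loc[pid] = np.clip(vals, 0.0, 1.0)
        truth.snp_probes[pid] = {"k": k, "genotypes": geno.copy()}
    return dataset


def inject_detection_failures(dataset: MultiTissueDataset,
                              config: SimulationConfig,
                              bad_samples: Optional[Dict[str, Sequence[str]]] = None,
                              ) -> Tuple[Dict[str, pd.DataFrame], SyntheticTruth]:
    """Build per-tissue detection-p matrices with planted failures.

    A ``frac_detection_fail`` fraction of probes per tissue is designated
    bad: every entry of those rows fails (p > 0.01).  Optionally whole
    samples can be failed too.  Everything else draws p ~ U(0, 0.01).
    Returns the p-matrices and a truth object recording the planted targets.
    """
    rng = _substream(config.seed, 5)
    truth = SyntheticTruth()
    detp: Dict[str, pd.DataFrame] = {}
    for tissue in dataset.tissues:
        beta = dataset.betas[tissue]
        n, m = beta.shape
        p = rng.uniform(0.0, 0.01, size=(n, m))
        n_bad = int(round(config.frac_detection_fail * n))
        bad_rows = np.sort(rng.choice(n, size=n_bad, replace=False)) if n_bad else np.array([], dtype=int)
        if n_bad:
            p[bad_rows, :] = rng.uniform(0.02, 1.0, size=(n_bad, m))
        frame = pd.DataFrame(p, index=beta.index, columns=beta.columns)
        bad_cols = list((bad_samples or {}).get(tissue, []))
        for col in bad_cols:
            frame[col] = rng.uniform(0.02, 1.0, size=n)
        detp[tissue] = frame
        truth.detection_bad_probes[tissue] = [beta.index[i] for i in bad_rows]
        truth.detection_bad_samples[tissue] = bad_cols
    return detp, truth


def make_annotation(probes: Sequence[str],
                    truth: Optional[SyntheticTruth] = None,
                    frac_snp_proximal: float = 0.025,
                    frac_non_cpg: float = 0.003,
                    seed: int = 0) -> pd.DataFrame:
    """Synthetic probe annotation: SNP distances, context, positions.

    Planted SNP-cluster probes (when a truth is given) are annotated
    SNP-proximal (distance 0) so ancestry PCs computed on SNP-overlapping
    probes pick up genotype structure.
    """
    rng = _substream(seed, 6)
    n = len(probes)
    dist = np.where(rng.random(n) < frac_snp_proximal,
                    rng.integers(0, 6, size=n),
                    rng.integers(6, 5000, size=n)).astype(float)
    context = np.where(rng.random(n) < frac_non_cpg, "non_cpg", "cpg")
    ann = pd.DataFrame({
        "probe_id": list(probes),
        "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=n)],
        "pos": rng.integers(1, 2_000_000, size=n),
        "snp_distance_bp": dist,
        "context": context,
    })
    if truth is not None and truth.snp_probes:
        mask = ann["probe_id"].isin(truth.snp_probes)
        ann.loc[mask, "snp_distance_bp"] = 0.0
    return ann
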
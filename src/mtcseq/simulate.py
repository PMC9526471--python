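"""Synthetic FNAB / surgical-tissue count cohorts with a planted MTC signature.

Medullary thyroid carcinoma (MTC) has an extreme expression phenotype: its
marker genes (calcitonin pathway, neuroendocrine program) are essentially
silent in benign and non-MTC malignant thyroid nodules and very highly
expressed in MTC.  The generator emulates that regime: a set of signature
genes with low baseline expression is multiplicatively up-shifted in MTC
samples of BOTH the fine-needle-aspiration (FNAB) and surgical-tissue
cohorts, by log2 fold changes drawn from a configurable interval
(default [6, 10]).

Counts are negative-binomial with per-gene dispersion drawn once and shared
across cohorts, and per-sample library-size factors drawn log-normally.
Non-MTC samples are heterogeneous: a small nuisance signature separates
benign from non-MTC malignant nodules, so downstream specificity is tested
against within-class structure rather than a single homogeneous profile.

The default cohort sizes mirror the study design this pipeline exercises:
21 MTC + 462 non-MTC training FNAB, 97 surgical tissues (21 MTC), and a
blinded validation cohort of 21 MTC + 190 non-MTC FNAB, plus technical
replicate control samples sequenced alongside training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, META_COLUMNS

DEFAULT_COHORT_SIZES = {
    "train_fnab": (21, 462),
    "tissue": (21, 76),
    "valid_fnab": (21, 190),
}

#: Bethesda cytology categories assigned to the MTC training FNABs
#: (5 x III, 6 x IV, 6 x V, 4 x VI) and to the validation MTC FNABs
#: (8 x III, 6 x IV, 7 x V).
TRAIN_MTC_BETHESDA = ["III"] * 5 + ["IV"] * 6 + ["V"] * 6 + ["VI"] * 4
VALID_MTC_BETHESDA = ["III"] * 8 + ["IV"] * 6 + ["V"] * 7


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_genes : int
        Total number of genes.
    n_signature : int
        Number of planted MTC-signature genes (disjoint from null genes).
    signature_log2fc_range : (float, float)
        Interval from which each signature gene's log2 fold change
        (MTC vs non-MTC expected expression) is drawn uniformly.
    n_cassette : int
        Mandatory genes embedded in the signature: the first
        ``n_cassette_core`` are the legacy "cassette" panel, the remainder
        are "literature" genes.  Always a subset of the signature.
    cohort_sizes : dict
        ``{cohort: (n_mtc, n_non_mtc)}`` for ``train_fnab``, ``tissue``
        and ``valid_fnab``.
    libsize_lognormal_params : (float, float)
        Mean and sd of the log library-size factor.
    dispersion_gamma_params : (float, float)
        Shape and scale of the per-gene NB dispersion distribution.
    n_control_groups, n_control_replicates : int
        Technical replicate controls: groups x replicates-per-group.
    n_nuisance : float
        Genes carrying a benign-vs-malignant nuisance signal within the
        non-MTC class, with |log2FC| <= ``nuisance_log2fc_max``.
    """

    n_genes: int = 5000
    n_signature: int = 120
    signature_log2fc_range: tuple[float, float] = (6.0, 10.0)
    n_cassette: int = 34
    n_cassette_core: int = 5
    cohort_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    libsize_lognormal_params: tuple[float, float] = (0.0, 0.3)
    dispersion_gamma_params: tuple[float, float] = (2.0, 0.05)
    n_control_groups: int = 6
    n_control_replicates: int = 3
    n_nuisance: int = 50
    nuisance_log2fc_max: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_signature <= self.n_genes:
            raise ValueError("signature count must be in [0, n_genes]")
        if self.n_signature + self.n_nuisance > self.n_genes:
            raise ValueError("signature + nuisance genes exceed n_genes")
        if self.n_cassette > max(self.n_signature, 0) and self.n_signature > 0:
            raise ValueError("cassette genes must be a subset of the signature")
        if self.n_cassette_core > self.n_cassette:
            raise ValueError("core cassette larger than cassette")
        for name, (a, b) in self.cohort_sizes.items():
            if a < 1 or b < 1:
                raise ValueError(f"cohort {name!r} has non-positive size")
        lo, hi = self.signature_log2fc_range
        if lo > hi:
            raise ValueError("signature_log2fc_range must be ordered")
        shape, scale = self.dispersion_gamma_params
        if shape <= 0 or scale < 0:
            raise ValueError("dispersion gamma parameters must be positive")
        if self.n_control_groups < 1 or self.n_control_replicates < 1:
            raise ValueError("control design must have >= 1 group and replicate")


@dataclass
class GeneParams:
    """Ground-truth generating parameters, reconstructible from a SimConfig."""

    gene_ids: list[str]
    base_mean: np.ndarray          # expected expression in benign non-MTC
    dispersion: np.ndarray         # NB dispersion alpha per gene
    signature_genes: list[str]
    signature_log2fc: np.ndarray   # per signature gene, same order
    cassette_genes: list[str]      # n_cassette genes, first n_cassette_core "core"
    nuisance_genes: list[str]
    nuisance_log2fc: np.ndarray

    @property
    def core_cassette_genes(self) -> list[str]:
        return self.cassette_genes[:5]

    def profile(self, kind: str) -> np.ndarray:
        """Expected-expression vector for ``kind`` in
        {"MTC", "benign", "malignant"} (the latter two are non-MTC)."""
        mu = self.base_mean.copy()
        sig_idx = np.arange(len(self.signature_genes))
        if kind == "MTC":
            mu[sig_idx] *= 2.0 ** self.signature_log2fc
        elif kind == "malignant":
            nui_idx = np.arange(
                len(self.signature_genes),
                len(self.signature_genes) + len(self.nuisance_genes),
            )
            mu[nui_idx] *= 2.0 ** self.nuisance_log2fc
        elif kind != "benign":
            raise ValueError(f"unknown profile kind {kind!r}")
        return mu


def gene_params(config: SimConfig) -> GeneParams:
    """Draw (deterministically, from ``config.seed``) the per-gene truth.

    Signature genes occupy the first ``n_signature`` rows, nuisance genes
    the following ``n_nuisance`` rows; everything else is null.  Signature
    baseline means are drawn low (near-silent in non-MTC) so that 64- to
    1024-fold activation in MTC stays within a realistic count range.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    g = config.n_genes
    ids = [f"G{i + 1:05d}" for i in range(g)]
    base = rng.lognormal(mean=2.5, sigma=1.3, size=g)
    n_sig = config.n_signature
    base[:n_sig] = rng.lognormal(mean=0.0, sigma=0.7, size=n_sig)
    shape, scale = config.dispersion_gamma_params
    disp = np.maximum(rng.gamma(shape, scale, size=g), 1e-6)
    lo, hi = config.signature_log2fc_range
    sig_fc = rng.uniform(lo, hi, size=n_sig)
    nui = config.n_nuisance
    nui_fc = rng.uniform(-config.nuisance_log2fc_max,
                         config.nuisance_log2fc_max, size=nui)
    n_cas = min(config.n_cassette, n_sig)
    return GeneParams(
        gene_ids=ids,
        base_mean=base,
        dispersion=disp,
        signature_genes=ids[:n_sig],
        signature_log2fc=sig_fc,
        cassette_genes=ids[:n_cas],
        nuisance_genes=ids[n_sig:n_sig + nui],
        nuisance_log2fc=nui_fc,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) counts with var = mu + alpha*mu^2; Poisson when alpha~0."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-10
    if np.any(poisson):
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if np.any(nb):
        r = 1.0 / alpha[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def sample_counts(profiles: np.ndarray, config: SimConfig,
                  rng: np.random.Generator,
                  size_factors: np.ndarray | None = None) -> np.ndarray:
    """Draw one NB count column per column of expected-expression ``profiles``."""
    params = gene_params(config)
    profiles = np.atleast_2d(profiles.T).T  # genes x samples
    n = profiles.shape[1]
    if size_factors is None:
        m, s = config.libsize_lognormal_params
        size_factors = rng.lognormal(m, s, size=n)
    mu = profiles * size_factors[None, :]
    return _nb_draw(rng, mu, params.dispersion[:, None])


def _cohort_meta(cohort: str, labels: list[str], histology: list[str],
                 bethesda: list[str], start: int) -> pd.DataFrame:
    n = len(labels)
    return pd.DataFrame({
        "sample_id": [f"{cohort}_{start + i:04d}" for i in range(n)],
        "cohort": cohort,
        "label": labels,
        "bethesda": bethesda,
        "replicate_group": [None] * n,
        "dilution_fraction": [np.nan] * n,
        "histology": histology,
    })


def simulate_cohorts(config: SimConfig) -> CountMatrix:
    """Generate the concatenated training-FNAB, tissue and validation-FNAB
    cohorts.

    MTC samples of both FNAB and tissue cohorts carry the planted signature
    (the same drawn log2 fold change per gene in both contexts); non-MTC
    samples are a benign/malignant mixture differing in the nuisance genes.
    Identical config (including seed) yields an identical matrix.
    """
    config.validate()
    params = gene_params(config)
    rng = np.random.default_rng([config.seed, 202])
    profiles = {k: params.profile(k) for k in ("MTC", "benign", "malignant")}

    blocks, metas = [], []
    for cohort in ("train_fnab", "tissue", "valid_fnab"):
        n_mtc, n_non = config.cohort_sizes[cohort]
        # non-MTC heterogeneity: alternate benign / non-MTC-malignant
        non_kinds = ["benign" if i % 2 == 0 else "malignant"
                     for i in range(n_non)]
        kinds = ["MTC"] * n_mtc + non_kinds
        prof = np.column_stack([profiles[k] for k in kinds])
        blocks.append(sample_counts(prof, config, rng))
        labels = ["MTC"] * n_mtc + ["non-MTC"] * n_non
        if cohort == "train_fnab" and n_mtc == 21:
            beth_mtc = list(TRAIN_MTC_BETHESDA)
        elif cohort == "valid_fnab" and n_mtc == 21:
            beth_mtc = list(VALID_MTC_BETHESDA)
        else:
            beth_mtc = [["III", "IV", "V", "VI"][i % 4] for i in range(n_mtc)]
        if cohort == "tissue":
            beth = ["NA"] * (n_mtc + n_non)
        else:
            beth_non = [["III", "IV", "V", "VI"][i % 4] for i in range(n_non)]
            beth = beth_mtc + beth_non
        histology = ["MTC"] * n_mtc + non_kinds
        metas.append(_cohort_meta(cohort, labels, histology, beth, 0))

    counts = np.hstack(blocks)
    meta = pd.concat(metas, ignore_index=True)
    return CountMatrix(counts=counts, gene_ids=params.gene_ids, sample_meta=meta)


def simulate_controls(config: SimConfig) -> CountMatrix:
    """Technical replicate control samples.

    Each replicate group shares a single underlying expected-expression
    vector (a benign-like or MTC-like profile with group-specific per-gene
    jitter); replicates within a group differ only by NB sampling noise and
    library size.  Groups alternate non-MTC-like and MTC-like so control
    scores span the decision axis.
    """
    config.validate()
    params = gene_params(config)
    rng = np.random.default_rng([config.seed, 303])
    blocks, metas = [], []
    for g in range(config.n_control_groups):
        kind = "MTC" if g % 2 == 1 else "benign"
        # distinct control pools: each group is its own biological material,
        # so per-gene profile jitter is substantial relative to NB noise
        jitter = rng.lognormal(0.0, 0.6, size=config.n_genes)
        profile = params.profile(kind) * jitter
        prof = np.column_stack([profile] * config.n_control_replicates)
        blocks.append(sample_counts(prof, config, rng))
        n = config.n_control_replicates
        meta = _cohort_meta(
            "control",
            ["MTC" if kind == "MTC" else "non-MTC"] * n,
            [kind] * n,
            ["NA"] * n,
            start=0,
        )
        meta["sample_id"] = [f"control_g{g + 1}_r{r + 1}" for r in range(n)]
        meta["replicate_group"] = f"g{g + 1}"
        metas.append(meta)
    return CountMatrix(
        counts=np.hstack(blocks),
        gene_ids=params.gene_ids,
        sample_meta=pd.concat(metas, ignore_index=True),
    )


def dilute_sample(mtc_profile: np.ndarray, benign_profile: np.ndarray,
                  fraction_benign: float) -> np.ndarray:
    """Convex combination of expected-expression vectors.

    Emulates mixing tumor RNA with benign RNA before sequencing:
    ``(1 - f) * mtc + f * benign`` on the expected-expression scale,
    applied before count sampling.
    """
    if not 0.0 <= fraction_benign <= 1.0:
        raise ValueError("fraction_benign must be in [0, 1]")
    mtc_profile = np.asarray(mtc_profile, dtype=float)
    benign_profile = np.asarray(benign_profile, dtype=float)
    if mtc_profile.shape != benign_profile.shape:
        raise ValueError("profiles must have the same length")
    return (1.0 - fraction_benign) * mtc_profile + fraction_benign * benign_profile
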
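"""Synthetic scRNA-seq counts with planted metabolic structure and dropout.

The generator emulates the statistical regime the pipeline is built for:
negative-binomial counts with lognormal library sizes, two (or more) cell
populations whose mean programs differ on the genes of one toy-model branch
versus the other, decoy non-metabolic genes providing whole-transcriptome
context, co-regulated gene *programs* planting known correlations, and
independent Bernoulli dropout planting false zeros.  Together with a toy
model preset it yields an end-to-end fixture for the full pipeline with
known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model_core import MetabolicModel, make_toy_model
from .sc_preprocess import ExpressionMatrix

logger = logging.getLogger("scflux.synthetic_data")


@dataclass
class CorrelatedPair:
    """Two genes driven by a shared lognormal program factor.

    ``target_rho`` is the Spearman correlation the pair should show on the
    normalised pre-dropout matrix.  The factor also drives ``program_width``
    decoy genes so the program is visible to the cell-similarity graph —
    a factor expressed in two genes only would be invisible to denoising.
    """

    gene_a: str
    gene_b: str
    target_rho: float = 0.8
    program_width: int = 16
    factor_sd: float = 1.2

    def __post_init__(self):
        if not (-1.0 <= self.target_rho <= 1.0):
            raise ValidationError("target_rho must be in [-1, 1]")


@dataclass
class CellCycleSim:
    """Optional planted cell-cycle programs (fractions must sum to 1)."""

    fractions: dict = field(default_factory=lambda: {"G1": 0.6, "S": 0.2, "G2M": 0.2})
    n_signature_genes: int = 20
    upshift: float = 8.0

    def __post_init__(self):
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("cell-cycle fractions must sum to 1")


@dataclass
class SimSpec:
    """Full description of one simulated dataset.

    ``populations`` maps each label to a gene→mean dict (genes absent from a
    population's dict default to 0).  ``nb_dispersion`` is the NB shape θ
    (var = μ + μ²/θ); ``library_size_spread`` is the σ of the lognormal
    per-cell scaling; ``dropout_rate`` the independent zero-inflation
    probability.
    """

    n_cells_per_population: int = 100
    populations: list = field(default_factory=list)  # [(label, {gene: mean})]
    nb_dispersion: float = 10.0
    dropout_rate: float = 0.4
    library_size_spread: float = 0.25
    correlated_pairs: list = field(default_factory=list)  # [CorrelatedPair]
    cell_cycle: CellCycleSim | None = None
    dropout_model: str = "independent"  # or "logistic" (mean-dependent)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValidationError("dropout_rate must be a probability")
        if self.nb_dispersion <= 0 or self.library_size_spread <= 0:
            raise ValidationError("nb_dispersion and library_size_spread must be positive")
        labels = [lab for lab, _ in self.populations]
        if len(set(labels)) != len(labels):
            raise ValidationError("population labels must be unique")
        for _, means in self.populations:
            if any(m < 0 for m in means.values()):
                raise ValidationError("gene means must be nonnegative")
        if self.dropout_model not in ("independent", "logistic"):
            raise ValidationError("dropout_model must be 'independent' or 'logistic'")


@dataclass
class SimResult:
    """Observed counts, pre-dropout truth, and ground-truth annotations."""

    observed: ExpressionMatrix
    truth: ExpressionMatrix
    labels: pd.Series  # cell id -> population label
    phases: pd.Series | None = None  # cell id -> planted cycle phase


def default_sim_spec(
    model: MetabolicModel,
    n_cells_per_population: int = 100,
    dropout_rate: float = 0.4,
    n_decoy_genes: int = 300,
    branch_high: float = 15.0,
    branch_low: float = 3.0,
    n_marker_decoys: int = 100,
    seed: int = 0,
    cell_cycle: CellCycleSim | None = None,
) -> SimSpec:
    """Two populations on the branched toy model.

    Trunk genes are expressed at ``branch_high`` in both populations (so the
    objective is reachable everywhere); population ``popA`` expresses the
    B-branch genes 5× over population ``popB`` and vice versa for the
    C-branch.  ``n_marker_decoys`` of the decoy genes also differ 4× between
    populations (cell identities differ transcriptome-wide, not just
    metabolically); the remaining decoys are shared background.  One
    co-regulated program ties the dedicated pathway-like genes PRGA/PRGB
    (target Spearman 0.8); keeping the program off the model's genes leaves
    the planted flux structure undisturbed.
    """
    model_genes = sorted(model.genes())
    decoys = [f"DEC{i:04d}" for i in range(n_decoy_genes)]
    clash = set(decoys) & set(model_genes)
    if clash:
        raise ValidationError(f"decoy gene names collide with model genes: {sorted(clash)}")
    rng = np.random.default_rng(seed)
    # flat mean distribution: no single gene dominates total counts, so no
    # individual dropout event forms its own axis in the similarity space
    decoy_means = dict(zip(decoys, rng.lognormal(math.log(10.0), 0.4, n_decoy_genes)))
    # bidirectional marker panel: half the markers up in each population, so
    # the populations differ transcriptome-wide without skewing total counts
    markers_a = decoys[: n_marker_decoys // 2]
    markers_b = decoys[n_marker_decoys // 2 : n_marker_decoys]

    trunk = {"gT1", "gT2", "gT3"}
    branch_b = {"g1a", "g1b", "gPB"}
    branch_c = {"g2a", "g2b", "g2c", "g2d", "gPC"}
    known = trunk | branch_b | branch_c
    extra = {g: branch_high for g in model_genes if g not in known}

    program_genes = {"PRGA": 20.0, "PRGB": 20.0}

    def pop(branch_up: set, marker_up: bool) -> dict:
        means = dict(program_genes)
        for g in model_genes:
            if g in trunk:
                means[g] = branch_high
            elif g in branch_b:
                means[g] = branch_high if branch_up is branch_b else branch_low
            elif g in branch_c:
                means[g] = branch_high if branch_up is branch_c else branch_low
            else:
                means[g] = extra[g]
        own = markers_a if marker_up else markers_b
        for g in decoys:
            m = decoy_means[g]
            if g in own:
                m = m * 4.0
            means[g] = m
        return means

    return SimSpec(
        n_cells_per_population=n_cells_per_population,
        populations=[("popA", pop(branch_b, True)), ("popB", pop(branch_c, False))],
        dropout_rate=dropout_rate,
        correlated_pairs=[CorrelatedPair("PRGA", "PRGB", 0.8, program_width=16)],
        cell_cycle=cell_cycle,
        seed=seed,
    )


def _log_nb_noise_var(mu: float, theta: float, sd: float, n_quad: int = 15) -> float:
    """Conditional variance of log(X + 1/2), X ~ NB(mu·f, theta), over f.

    f is the lognormal program factor (log-sd ``sd``); Gauss–Hermite
    quadrature over its latent normal.  Used to deattenuate planted
    correlations (the delta-method value log1p(CV²) underestimates the
    small-count skew).
    """
    from scipy import stats

    zq, wq = np.polynomial.hermite_e.hermegauss(n_quad)
    wq = wq / wq.sum()
    total = 0.0
    for z, w in zip(zq, wq):
        m = mu * math.exp(sd * z - sd * sd / 2.0)
        hi = int(m + 10.0 * math.sqrt(m + m * m / theta)) + 10
        xs = np.arange(hi + 1)
        pmf = stats.nbinom.pmf(xs, theta, theta / (theta + m))
        pmf = pmf / pmf.sum()
        lx = np.log(xs + 0.5)
        mean = float(pmf @ lx)
        total += w * float(pmf @ (lx - mean) ** 2)
    return total


def simulate_counts(spec: SimSpec) -> SimResult:
    """Draw one dataset from a :class:`SimSpec` (bit-deterministic per seed)."""
    if not spec.populations:
        raise ValidationError("spec has no populations")
    if spec.n_cells_per_population < 1:
        raise ValidationError("need at least one cell per population")
    genes: list[str] = []
    for _, means in spec.populations:
        for g in means:
            if g not in genes:
                genes.append(g)
    if len(genes) < 2:
        raise ValidationError("need at least two genes")
    n_pops = len(spec.populations)
    n_cells = n_pops * spec.n_cells_per_population
    rng = np.random.default_rng(spec.seed)

    labels = []
    mean_mat = np.zeros((len(genes), n_cells))
    gidx = {g: i for i, g in enumerate(genes)}
    for p, (lab, means) in enumerate(spec.populations):
        sl = slice(p * spec.n_cells_per_population, (p + 1) * spec.n_cells_per_population)
        labels += [lab] * spec.n_cells_per_population
        for g, m in means.items():
            mean_mat[gidx[g], sl] = m

    cell_ids = [f"cell{(i + 1):04d}" for i in range(n_cells)]
    labels = pd.Series(labels, index=cell_ids, name="population")

    # planted cell-cycle programs: signature decoy genes upshifted per phase
    phases = None
    if spec.cell_cycle is not None:
        cc = spec.cell_cycle
        s_sig = [f"SGENE{i:02d}" for i in range(cc.n_signature_genes)]
        g2m_sig = [f"G2MGENE{i:02d}" for i in range(cc.n_signature_genes)]
        for g in s_sig + g2m_sig:
            genes.append(g)
            gidx[g] = len(genes) - 1
        mean_mat = np.vstack(
            [mean_mat, np.full((2 * cc.n_signature_genes, n_cells), 5.0)]
        )
        phase_names = list(cc.fractions)
        phase_draw = rng.choice(
            phase_names, size=n_cells, p=[cc.fractions[k] for k in phase_names]
        )
        for ph, sig in (("S", s_sig), ("G2M", g2m_sig)):
            cols = phase_draw == ph
            rows = [gidx[g] for g in sig]
            mean_mat[np.ix_(rows, cols)] *= cc.upshift
        phases = pd.Series(phase_draw, index=cell_ids, name="phase")

    # co-regulated programs: shared lognormal factor over the pair + a block
    # of decoy genes (so the similarity graph can see the program)
    for k, pair in enumerate(spec.correlated_pairs):
        for g in (pair.gene_a, pair.gene_b):
            if g not in gidx:
                raise ValidationError(f"correlated-pair gene {g!r} not in simulation")
        # Latent Pearson correlation: for bivariate normal latents the
        # Spearman of the pair is 6/pi * asin(r/2); NB sampling then
        # attenuates it, so the latent r is deattenuated by the classical
        # measurement-error factor sqrt(R_a R_b), with per-gene reliability
        # R_g = sd^2 / (sd^2 + V_g) and V_g the exact conditional variance
        # of log(X + 1/2) for X ~ NB(mu_g f, theta), averaged over f.
        sd = pair.factor_sd

        def reliability(g):
            mus = [m.get(g, 0.0) for _, m in spec.populations]
            mu = float(np.mean([m for m in mus if m > 0]) or 1.0)
            v = _log_nb_noise_var(mu, spec.nb_dispersion, sd)
            return sd * sd / (sd * sd + v)

        r = 2.0 * math.sin(math.pi * pair.target_rho / 6.0)
        r = float(np.clip(
            r / math.sqrt(reliability(pair.gene_a) * reliability(pair.gene_b)),
            -0.999, 0.999,
        ))
        z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]], size=n_cells).T
        fac_a = np.exp(sd * z[0] - sd * sd / 2.0)
        fac_b = np.exp(sd * z[1] - sd * sd / 2.0)
        mean_mat[gidx[pair.gene_a]] *= fac_a
        mean_mat[gidx[pair.gene_b]] *= fac_b
        # a co-regulated decoy block rides the same two factors, half activated
        # and half repressed: visible to the cell-similarity graph while
        # leaving total counts mean-neutral (exp(s) + exp(-s) ≈ 2 + s²)
        block = [
            g for g in genes if g.startswith("DEC")
        ][-(pair.program_width) * (k + 1):][: pair.program_width]
        for i, g in enumerate(block):
            z_g = z[0] if i % 2 == 0 else z[1]
            sign = 1.0 if (i // 2) % 2 == 0 else -1.0
            mean_mat[gidx[g]] *= np.exp(sign * sd * z_g - sd * sd / 2.0)

    lib = rng.lognormal(0.0, spec.library_size_spread, n_cells)
    mu = mean_mat * lib
    theta = spec.nb_dispersion
    lam = np.where(mu > 0, rng.gamma(theta, 1.0, mu.shape) * (mu / theta), 0.0)
    truth_counts = rng.poisson(lam).astype(float)

    if spec.dropout_rate > 0:
        if spec.dropout_model == "independent":
            drop = rng.random(mu.shape) < spec.dropout_rate
        else:
            # mean-dependent: logistic in log-mean, anchored so a gene at the
            # median mean drops at ~dropout_rate
            logmu = np.log1p(mu)
            x0 = np.median(logmu)
            p = spec.dropout_rate * 2.0 / (1.0 + np.exp(logmu - x0))
            drop = rng.random(mu.shape) < np.clip(p, 0.0, 1.0)
        observed_counts = np.where(drop, 0.0, truth_counts)
    else:
        observed_counts = truth_counts.copy()

    meta = pd.DataFrame({"population": labels}, index=cell_ids)
    if phases is not None:
        meta["true_phase"] = phases
    observed = ExpressionMatrix(list(genes), cell_ids, observed_counts, "raw", meta.copy())
    truth = ExpressionMatrix(list(genes), cell_ids, truth_counts, "raw", meta.copy())
    return SimResult(observed, truth, labels, phases)


@dataclass
class FixtureBundle:
    """Everything the full pipeline needs, with ground truth attached."""

    model: MetabolicModel
    counts: ExpressionMatrix
    truth: ExpressionMatrix
    labels: pd.Series
    phases: pd.Series | None
    spec: SimSpec


def fixture_analysis_configs(n_cells_per_population: int = 100, seed: int = 0):
    """Analysis settings matched to the fixture's population size.

    For cluster recovery the diffusion neighbourhood must be at population
    scale (knn ≈ half a population) so that smoothing noise cannot carve
    spurious subpopulations, and the clustering kNN graph dense enough that
    the population-level partition is among the Leiden candidates.  Local
    structure (e.g. planted co-regulated programs) is better preserved by
    the package's default, smaller neighbourhoods.

    Returns ``(DiffusionConfig, ClusterConfig)``.
    """
    from .clustering import ClusterConfig
    from .denoise import DiffusionConfig

    knn = max(15, (9 * n_cells_per_population) // 20)
    neighbors_k = max(15, (2 * n_cells_per_population) // 5)
    return (
        DiffusionConfig(knn=knn, t=3, seed=seed),
        ClusterConfig(neighbors_k=neighbors_k, seed=seed),
    )


def end_to_end_fixture(
    preset: str = "branched", spec: SimSpec | None = None, seed: int = 0, **spec_kwargs
) -> FixtureBundle:
    """Toy model + simulated counts whose gene namespace matches its GPRs."""
    model = make_toy_model(preset)
    if spec is None:
        spec = default_sim_spec(model, seed=seed, **spec_kwargs)
    sim_genes = {g for _, means in spec.populations for g in means}
    missing = model.genes() - sim_genes
    if missing:
        raise ValidationError(f"simulation lacks model genes: {sorted(missing)}")
    sim = simulate_counts(spec)
    return FixtureBundle(model, sim.observed, sim.truth, sim.labels, sim.phases, spec)
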
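"""Synthetic-data generators emulating the xenologous-replacement study design.

Every generator is a pure function of its parameters and seed and returns,
alongside the data, a :class:`SyntheticTruth` record of the generating
parameters so downstream estimators can be tested for parameter recovery.

The default strain table mirrors the study conditions: 35 ortholog
replacement strains of which 6 hit an abundance barrier; melting
temperatures uniform on 42-63 degC (the mesophilic range); catalytic
efficiencies spanning two orders of magnitude around the wild-type value;
abundance positively coupled to Tm; growth rates generated from the
saturating flux-fitness landscape plus Gaussian noise.

Barrier strains model proteostatic degradation/aggregation of the foreign
protein: their *functional* naive dosage is suppressed nearly to zero (hence
near-zero growth), while the *measured* total-lysate abundance is only
partially suppressed — total lysate also counts nonfunctional protein —
with values below the detection limit reported as missing ("n.d.").  After
the simulated evolution phase the suppression is lifted.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .fitness_landscape import STRAIN_COLUMNS, flux_fitness
from .kinetics_growth import gompertz_od
from .proteome import GeneGroupSet
from .seqprops import _FAMILY, _STOP_SYMBOL, Thermogram

__all__ = [
    "SyntheticTruth",
    "gen_strain_table",
    "gen_proteomes",
    "gen_growth_curves",
    "gen_thermogram",
    "gen_codon_reference",
    "default_gene_groups",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters recorded verbatim for round-trip tests."""

    seed: int
    a: float | None = None
    b: float | None = None
    barrier_ids: tuple[str, ...] = ()
    suppression_measured: float | None = None
    suppression_functional: float | None = None
    detection_limit: float | None = None
    noise_sd: float | None = None
    planted_shifts: dict | None = None
    inter_strain_corr: float | None = None
    extra: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["barrier_ids"] = list(self.barrier_ids)
        return {k: v for k, v in d.items() if v is not None and v != []}


def gen_strain_table(
    n_strains: int = 35,
    n_barrier: int = 6,
    a: float = 0.6,
    b: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    wt_kcat_over_km: float = 1.0,
    suppression_measured: float = 0.5,
    suppression_functional: float = 0.01,
    detection_limit: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a strain property table with a designated barrier subset.

    Parameters
    ----------
    a, b
        Plateau (h^-1) and half-saturation (dosage units) of the generating
        flux-fitness landscape.
    noise_sd
        SD of additive Gaussian noise on growth rates (h^-1).
    suppression_measured, suppression_functional
        Multipliers applied to barrier strains' naive measured total
        abundance and functional (growth-determining) abundance.
    detection_limit
        Measured abundances below this WT fraction are reported missing.
    """
    if not (0 <= n_barrier <= n_strains):
        raise ValueError("need 0 <= n_barrier <= n_strains")
    rng = np.random.default_rng(seed)
    ids = [f"DHFR-{i}" for i in range(1, n_strains + 1)]

    tm = rng.uniform(42.0, 63.0, n_strains)
    kcat_over_km = wt_kcat_over_km * 10.0 ** rng.uniform(-1.0, 1.0, n_strains)
    # abundance increases with Tm (proteostasis degrades less stable folds faster)
    base_abund = np.exp((tm - 55.0) / 8.0) * rng.lognormal(0.0, 0.4, n_strains)

    # barrier strains are drawn from the upper half of intrinsic dosage: the
    # striking study phenotype is high-activity enzymes whose strains barely
    # grow, i.e. clear off-curve outliers rather than low-dosage strains that
    # would sit near the origin anyway
    base_dosage = base_abund * kcat_over_km
    eligible = np.argsort(base_dosage)[int(0.6 * n_strains) :]
    if n_barrier > eligible.size:
        eligible = np.argsort(base_dosage)
    barrier_idx = np.sort(rng.choice(eligible, size=n_barrier, replace=False))
    is_barrier = np.zeros(n_strains, dtype=bool)
    is_barrier[barrier_idx] = True
    # a subset of barrier strains collapses below the detection limit even in
    # total lysate (the study's "n.d." strains); the rest stay detectable but
    # partially suppressed
    collapsed = is_barrier & (rng.random(n_strains) < 1.0 / 3.0)

    functional_naive = np.where(is_barrier, base_abund * suppression_functional, base_abund)
    measured_total_naive = np.where(
        collapsed,
        base_abund * suppression_functional,
        np.where(is_barrier, base_abund * suppression_measured, base_abund),
    )
    measured_total_evolved = base_abund * rng.lognormal(np.log(1.25), 0.15, n_strains)
    soluble_frac = rng.uniform(0.5, 0.9, n_strains)
    measured_sol_naive = measured_total_naive * soluble_frac
    measured_sol_evolved = measured_total_evolved * soluble_frac

    dosage_naive = functional_naive * kcat_over_km
    dosage_evolved = measured_total_evolved * kcat_over_km
    growth_naive = flux_fitness(dosage_naive, a, b)
    growth_evolved = flux_fitness(dosage_evolved, a, b)
    if noise_sd > 0:
        growth_naive = np.maximum(growth_naive + rng.normal(0, noise_sd, n_strains), 0.0)
        growth_evolved = np.maximum(growth_evolved + rng.normal(0, noise_sd, n_strains), 0.0)

    # promoter activation is a starvation signature: inverse in functional dosage
    pa_scale = 2000.0
    promoter_naive = pa_scale / (1.0 + dosage_naive / b) * rng.lognormal(0.0, 0.1, n_strains)
    promoter_evolved = pa_scale / (1.0 + dosage_evolved / b) * rng.lognormal(0.0, 0.1, n_strains)

    # barrier strains carry more extreme net charge (away from the optimum -3.5)
    q = rng.normal(-3.5, 1.5, n_strains)
    signs = rng.choice([-1.0, 1.0], n_strains)
    q = np.where(is_barrier, -3.5 + signs * rng.uniform(4.0, 7.0, n_strains), q)

    nd = measured_total_naive < detection_limit
    table = pd.DataFrame(
        {
            "strain_id": ids,
            "species": [f"species_{i}" for i in range(1, n_strains + 1)],
            "growth_rate_naive": growth_naive,
            "growth_rate_evolved": growth_evolved,
            "tm_c": tm,
            "kcat_over_km": kcat_over_km,
            "abundance_total_naive": np.where(nd, np.nan, measured_total_naive),
            "abundance_total_evolved": measured_total_evolved,
            "abundance_soluble_naive": np.where(nd, np.nan, measured_sol_naive),
            "abundance_soluble_evolved": measured_sol_evolved,
            "promoter_activity_naive": promoter_naive,
            "promoter_activity_evolved": promoter_evolved,
            "net_charge": q,
            "gc_percent": rng.normal(52.0, 2.0, n_strains),
            "identity_percent": rng.uniform(29.0, 96.0, n_strains),
            "cai": rng.uniform(0.55, 0.8, n_strains),
            "mrna_dg": rng.normal(-8.0, 2.0, n_strains),
        },
        columns=STRAIN_COLUMNS,
    )
    truth = SyntheticTruth(
        seed=seed,
        a=a,
        b=b,
        barrier_ids=tuple(ids[i] for i in barrier_idx),
        suppression_measured=suppression_measured,
        suppression_functional=suppression_functional,
        detection_limit=detection_limit,
        noise_sd=noise_sd,
    )
    return table, truth


def default_gene_groups(
    n_genes: int = 2000, n_groups: int = 20, group_size: int = 50, seed: int = 0
) -> GeneGroupSet:
    """Disjointly sampled gene groups over a synthetic gene universe."""
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    picks = rng.choice(n_genes, size=(n_groups, group_size), replace=False)
    return GeneGroupSet(
        groups={f"group_{g:02d}": tuple(genes[i] for i in picks[g]) for g in range(n_groups)}
    )


def gen_proteomes(
    n_genes: int = 2000,
    groups: GeneGroupSet | None = None,
    planted_shifts: dict[str, float] | None = None,
    inter_strain_corr: float = 0.4,
    strains: tuple[str, ...] = ("DHFR-22", "DHFR-23", "DHFR-35", "DHFR-38", "DHFR-39"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate pre/post relative-abundance matrices with planted group shifts.

    Background LRPA is standard normal; strains within a condition share a
    per-gene latent component giving expected pairwise correlation
    ``inter_strain_corr``.  ``planted_shifts`` maps group names to the z-shift
    added to member genes in the *post* matrix.  Returned matrices hold
    relative abundances (10**Y), the dialect the analysis ingests.
    """
    planted_shifts = dict(planted_shifts or {})
    if groups is None and planted_shifts:
        raise ValueError("planted shifts given without a gene-group set")
    if groups is not None:
        unknown = [g for g in planted_shifts if g not in groups]
        if unknown:
            raise ValueError(f"planted shift on unknown group(s): {unknown}")
    if not (0.0 <= inter_strain_corr < 1.0):
        raise ValueError("inter_strain_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    rho = inter_strain_corr

    def condition_matrix() -> np.ndarray:
        latent = rng.normal(0.0, 1.0, (n_genes, 1))
        eps = rng.normal(0.0, 1.0, (n_genes, len(strains)))
        return np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps

    y_pre = condition_matrix()
    y_post = condition_matrix()
    if groups is not None:
        index = {g: i for i, g in enumerate(genes)}
        for name, dz in planted_shifts.items():
            rows = [index[g] for g in groups.groups[name] if g in index]
            y_post[rows, :] += dz
    pre = pd.DataFrame(10.0 ** y_pre, index=genes, columns=list(strains))
    post = pd.DataFrame(10.0 ** y_post, index=genes, columns=list(strains))
    truth = SyntheticTruth(
        seed=seed,
        planted_shifts=planted_shifts,
        inter_strain_corr=rho,
        extra={"n_genes": n_genes, "strains": list(strains)},
    )
    return pre, post, truth


def gen_growth_curves(
    rate: float = 0.6,
    lag: float = 1.0,
    asymptote: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    od0: float = 0.01,
    duration_h: float = 10.0,
    interval_h: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Gompertz OD600 trajectory sampled at 20-min intervals over 10 h."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    t = np.arange(0.0, duration_h + 1e-9, interval_h)
    amplitude = np.log(asymptote / od0)
    if rate == 0 or amplitude <= 0:
        od = np.full_like(t, od0)
    else:
        od = gompertz_od(t, od0, rate, lag, amplitude)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = np.maximum(od + rng.normal(0, noise_sd, od.shape), 1e-6)
    return pd.DataFrame({"time_h": t, "od600": od})


def gen_thermogram(
    tm: float = 55.0,
    width: float = 2.5,
    baseline_slope: float = 0.0,
    grid_step: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_height: float = 1.0,
    t_min: float = 20.0,
    t_max: float = 80.0,
) -> Thermogram:
    """Gaussian unfolding transition on an affine baseline over a 20-80 degC scan."""
    if not (t_min <= tm <= t_max):
        raise ValueError(f"tm {tm} outside scan range [{t_min}, {t_max}]")
    t = np.arange(t_min, t_max + grid_step / 2.0, grid_step)
    signal = peak_height * np.exp(-0.5 * ((t - tm) / width) ** 2) + baseline_slope * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0, noise_sd, signal.shape)
    return Thermogram(temperature=t, signal=signal)


def gen_codon_reference(
    seed: int = 0,
    n_codons: int = 159,
    mutation_fractions: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5),
) -> tuple[str, dict[str, str]]:
    """Random reference ORF with skewed codon usage plus mutated protein variants.

    The ORF starts with ATG and ends with a stop codon; per amino acid, codon
    choice follows a Dirichlet-skewed distribution so the usage signature has
    clear family-maximal codons.  Variants substitute the given fraction of
    residues (no gaps) for identity-calibration tests.
    """
    rng = np.random.default_rng(seed)
    aas = sorted(set(_FAMILY) - {_STOP_SYMBOL})
    codon_probs = {
        aa: rng.dirichlet(np.full(len(_FAMILY[aa]), 0.3)) for aa in aas
    }
    protein = ["M"] + [aas[i] for i in rng.integers(0, len(aas), n_codons - 1)]
    codons = []
    for aa in protein:
        fam = _FAMILY[aa]
        codons.append(fam[rng.choice(len(fam), p=codon_probs[aa])])
    codons.append("TAA")
    orf = "".join(codons)
    variants: dict[str, str] = {}
    for frac in mutation_fractions:
        seq = list(protein)
        n_mut = int(round(frac * len(seq)))
        if n_mut:
            pos = rng.choice(len(seq), size=n_mut, replace=False)
            for p in pos:
                choices = [a for a in aas if a != seq[p]]
                seq[p] = choices[rng.integers(0, len(choices))]
        variants[f"variant_{int(round(frac * 100)):03d}"] = "".join(seq)
    return orf, variants
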
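"""Synthetic bacteria-phage data generator.

The population model couples logistic bacterial growth to phage predation
with an Erlang-distributed latent period, optional lysogenization and a
slow flow of susceptible cells into a phage-resistant class:

    S'  = r S (1 - N/K) - a S V
    I1' = (1 - p_lys) a S V - (n/tau) I1
    Ij' = (n/tau) (I_{j-1} - I_j)              j = 2..n
    L'  = p_lys a S V + r_L L (1 - N/K)
    R'  = m S + r R (1 - N/K)
    V'  = beta (n/tau) I_n - a S V - delta V

with N = S + sum(I) + L + R.  The n latency compartments give an Erlang(n)
lysis-time distribution with mean ``tau``; lysogens (L) and resistant
cells (R) are phage-inert and grow logistically.  Optical density is
``c_od * N`` plus additive Gaussian noise floored at zero; plated titers
are Poisson counts.

The system is stiff when a dense culture collapses (the effective
adsorption rate ``a * V`` can exceed 10^3 per hour while growth rates are
of order 1), so integration uses the LSODA solver, which switches to a
BDF method in the stiff regime.  The solver is deterministic: identical
parameters and seed reproduce output bit-for-bit on a given platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .io_tables import AnnotatedGenome, GeneRecord, GrowthCurve, KillCurvePanel, SurvivalRecord, TiterSeries

__all__ = [
    "SimParams",
    "PRESET_30C",
    "PRESET_37C",
    "Trajectory",
    "integrate",
    "simulate_kill_curves",
    "simulate_one_step",
    "one_step_assay",
    "simulate_spot_counts",
    "simulate_genome",
    "simulate_survival",
]

START_CODONS = ("ATG", "GTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimParams:
    """Rate constants and observation noise for the population model.

    Units: rates per hour, densities CFU/mL or PFU/mL, adsorption constant
    mL/(cell*h).  Defaults describe a fast-growing *Burkholderia*-like host
    and a temperate podophage with a 1.5 h latent period and a burst size
    of 296 virions per cell.
    """

    r: float = 0.35         # susceptible growth rate, per h
    r_L: float = 0.35       # lysogen growth rate, per h
    K: float = 1.5e9        # carrying capacity, CFU/mL
    a: float = 1e-8         # adsorption rate constant, mL/(cell*h)
    tau: float = 1.5        # mean latent period, h
    beta: float = 296.0     # burst size, virions per lysed cell
    n_stages: int = 5       # Erlang latency stages
    p_lys: float = 0.01     # lysogenization probability per infection
    m: float = 1e-8         # susceptible -> resistant emergence rate, per h
    delta: float = 0.0      # free phage decay, per h
    c_od: float = 1e-9      # OD600 per CFU/mL
    sigma_od: float = 0.01  # additive OD noise s.d.
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r", "r_L", "a", "tau", "beta", "m", "delta", "c_od", "sigma_od"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_lys <= 1:
            raise ValueError("p_lys must be in [0, 1]")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.K <= 0:
            raise ValueError("K must be positive")


# Scenario presets for microplate kill curves.  Temperature is not
# mechanistic in the model; the two presets encode the contrast between a
# strongly lytic infection (efficient adsorption, full burst, rare
# lysogeny) and a weakly virulent one (inefficient adsorption, reduced
# burst, frequent lysogeny).  Hosts grow slower but to a higher density
# in the cooler scenario.
PRESET_37C = SimParams()
PRESET_30C = SimParams(r=0.3, r_L=0.3, K=1.8e9, a=1e-10, beta=100.0, p_lys=0.5)


@dataclass
class Trajectory:
    """Dense model output on the requested grid.

    ``states`` columns: S, I1..In, L, R, V, then two bookkeeping
    accumulators (cells ever entering the infected class, cumulative phage
    released by lysis).
    """

    times: np.ndarray
    states: np.ndarray
    n_stages: int

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def infected(self) -> np.ndarray:
        return self.states[:, 1 : 1 + self.n_stages].sum(axis=1)

    @property
    def L(self) -> np.ndarray:
        return self.states[:, 1 + self.n_stages]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 2 + self.n_stages]

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 3 + self.n_stages]

    @property
    def cells(self) -> np.ndarray:
        """Total intact cells N = S + sum(I) + L + R."""
        return self.S + self.infected + self.L + self.R

    @property
    def cum_infected(self) -> np.ndarray:
        return self.states[:, 4 + self.n_stages]

    @property
    def cum_released(self) -> np.ndarray:
        return self.states[:, 5 + self.n_stages]


def _rhs(t: float, y: np.ndarray, p: SimParams, a: float) -> np.ndarray:
    n = p.n_stages
    pos = np.maximum(y, 0.0)  # guard against tiny negative solver excursions
    S = pos[0]
    I = pos[1 : 1 + n]
    L = pos[1 + n]
    R = pos[2 + n]
    V = pos[3 + n]
    N = S + I.sum() + L + R
    logistic = 1.0 - N / p.K
    inf_flux = a * S * V
    k = n / p.tau
    dy = np.empty_like(y)
    dy[0] = p.r * S * logistic - inf_flux
    dy[1] = (1.0 - p.p_lys) * inf_flux - k * I[0]
    if n > 1:
        dy[2 : 1 + n] = k * (I[:-1] - I[1:])
    released = p.beta * k * I[-1]
    dy[1 + n] = p.p_lys * inf_flux + p.r_L * L * logistic
    dy[2 + n] = p.m * S + p.r * R * logistic
    dy[3 + n] = released - inf_flux - p.delta * V
    dy[4 + n] = (1.0 - p.p_lys) * inf_flux  # cells ever infected
    dy[5 + n] = released                    # cumulative phage released
    return dy


def integrate(
    params: SimParams,
    s0: float,
    v0: float,
    t_end: float,
    dt_out: float,
    a_off_after: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> Trajectory:
    """Integrate the model from (S=s0, V=v0).

    ``a_off_after`` optionally zeroes the adsorption constant from that
    time on, emulating the dilution step of a synchronized-infection
    protocol that stops readsorption of progeny; the integration is split
    at that time so the solver never steps across the discontinuity.
    Output states are floored at zero.  Raises if integration fails or the
    state becomes non-finite.
    """
    if dt_out <= 0 or t_end <= 0:
        raise ValueError("t_end and dt_out must be positive")
    n = params.n_stages
    y = np.zeros(6 + n)
    y[0] = s0
    y[3 + n] = v0

    n_out = math.ceil(t_end / dt_out - 1e-9)
    times = np.arange(n_out + 1) * dt_out

    if a_off_after is not None and 0.0 < a_off_after < times[-1]:
        legs = [(0.0, a_off_after, params.a), (a_off_after, times[-1], 0.0)]
    else:
        legs = [(0.0, times[-1], params.a)]

    states = np.empty((n_out + 1, y.size))
    states[0] = y
    eps = 1e-12
    for t0, t1, a in legs:
        mask = (times > t0 + eps) & (times <= t1 + eps)
        seg = times[mask]
        t_eval = seg if seg.size and abs(seg[-1] - t1) < eps else np.append(seg, t1)
        sol = solve_ivp(
            _rhs, (t0, t1), y, t_eval=t_eval, args=(params, a),
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise FloatingPointError(
                f"integration failed on [{t0}, {t1}] h: {sol.message}"
            )
        states[np.nonzero(mask)[0]] = sol.y[:, : seg.size].T
        y = sol.y[:, -1]
    np.maximum(states, 0.0, out=states)
    return Trajectory(times=times, states=states, n_stages=n)


def simulate_kill_curves(
    params: SimParams,
    mois: Sequence[float],
    t_end: float = 48.0,
    dt_out: float = 1.0,
    cfu0: float = 1e6,
    temperature: str = "",
) -> KillCurvePanel:
    """Simulate a plate-reader kill-curve panel.

    One noiseless uninfected control plus one noisy OD600 curve per MOI,
    all on the same output grid.  ``cfu0`` is the inoculum density
    (default 1e6 CFU/mL, a 1:100 subculture dilution).
    """
    if any(m <= 0 for m in mois):
        raise ValueError("MOIs must be positive")
    rng = np.random.default_rng(params.seed)
    control_traj = integrate(params, cfu0, 0.0, t_end, dt_out)
    control = GrowthCurve(
        control_traj.times, params.c_od * control_traj.cells, label="control"
    )
    curves = []
    for moi in mois:
        traj = integrate(params, cfu0, moi * cfu0, t_end, dt_out)
        od = params.c_od * traj.cells
        if params.sigma_od > 0:
            od = od + rng.normal(0.0, params.sigma_od, size=od.size)
        od = np.maximum(od, 0.0)
        curves.append((float(moi), GrowthCurve(traj.times, od, label=f"{moi:g}")))
    return KillCurvePanel(control=control, phage_curves=curves, temperature=temperature)


def _poisson_titer(
    v: float, rng: np.random.Generator, spot_volume_ul: float, replicates: int = 3
) -> float:
    """Plated-count observation of a true titer ``v`` (PFU/mL).

    Chooses the serial dilution whose expected spot count lands in
    [300, 3000) and averages ``replicates`` independent Poisson spot
    counts, mirroring titration in technical triplicate; reports
    mean count * 10^d / volume.
    """
    vol_ml = spot_volume_ul / 1000.0
    mean = v * vol_ml
    if mean <= 0:
        return 0.0
    d = max(0, math.floor(math.log10(mean / 300.0)) if mean > 300 else 0)
    counts = rng.poisson(mean / 10**d, size=replicates)
    return float(counts.mean()) * 10**d / vol_ml


def simulate_one_step(
    params: SimParams,
    cfu0: float,
    moi: float,
    dt_out: float = 0.5,
    t_end: float = 6.0,
    adsorption_time: float = 0.5,
    poisson: bool = True,
    spot_volume_ul: float = 5.0,
) -> TiterSeries:
    """Simulate a one-step (single synchronized infection cycle) titer series.

    Phage adsorb to the culture for ``adsorption_time`` hours, after which
    the adsorption term is switched off — the model analogue of the large
    dilution used in synchronized-infection protocols to stop readsorption
    of progeny.  Observed titers are Poisson plate counts of the free-phage
    density unless ``poisson`` is False.  ``initial_phage`` is moi * cfu0.
    """
    if cfu0 <= 0 or moi <= 0:
        raise ValueError("cfu0 and moi must be positive")
    rng = np.random.default_rng(params.seed)
    v0 = moi * cfu0
    traj = integrate(params, cfu0, v0, t_end, dt_out, a_off_after=adsorption_time)
    if poisson:
        pfu = np.array([_poisson_titer(v, rng, spot_volume_ul) for v in traj.V])
    else:
        pfu = traj.V.copy()
    return TiterSeries(traj.times, pfu, initial_phage=v0)


def one_step_assay(
    seed: int = 0, beta: float = 296.0, tau: float = 1.5, poisson: bool = True
) -> TiterSeries:
    """Simulate a standard synchronized one-step growth experiment.

    Study conditions: a ~3e7 CFU/mL subculture, phage added at MOI 0.1,
    efficient adsorption (99% of phage adsorbed within the 30 min
    adsorption period), readsorption stopped by dilution, samples titered
    every 30 min for 6 h.  Lysis timing in a synchronized single cycle is
    sharp (CV ~9%), modeled with 120 Erlang stages; lysogenization and
    phage decay are negligible on this time scale.
    """
    params = SimParams(
        r=0.8, K=1.5e9, a=3e-7, tau=tau, beta=beta, n_stages=120,
        p_lys=0.0, m=0.0, delta=0.0, seed=seed,
    )
    return simulate_one_step(
        params, cfu0=3e7, moi=0.1, dt_out=0.5, t_end=6.0,
        adsorption_time=0.5, poisson=poisson,
    )


def simulate_spot_counts(
    true_pfu_per_ml: float,
    dilution_exponents: Sequence[int],
    spot_volume_ul: float = 5.0,
    seed: int = 0,
) -> list[int]:
    """Poisson plaque counts for spots of a tenfold dilution series."""
    if true_pfu_per_ml < 0:
        raise ValueError("titer must be non-negative")
    if spot_volume_ul <= 0:
        raise ValueError("spot volume must be positive")
    rng = np.random.default_rng(seed)
    vol_ml = spot_volume_ul / 1000.0
    return [
        int(rng.poisson(true_pfu_per_ml * 10.0 ** (-d) * vol_ml))
        for d in dilution_exponents
    ]


def _random_codon(rng: np.random.Generator, gc: float, exclude_stops: bool = True) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        codon = "".join(rng.choice(list("ACGT"), p=p) for _ in range(3))
        if not exclude_stops or codon not in STOP_CODONS:
            return codon


def simulate_genome(
    seed: int,
    length: int = 20000,
    n_genes: int = 10,
    gc: float = 0.654,
    terminal_repeat: int = 9,
    gene_length_range: tuple[int, int] = (150, 900),
    p_gtg_start: float = 0.2,
) -> tuple[AnnotatedGenome, dict]:
    """Generate an annotated genome with fully known ground truth.

    Non-overlapping genes with known start/stop codons and strands are
    planted on a random background of the requested G+C fraction; the
    first ``terminal_repeat`` bases are copied onto the end of the
    sequence, producing the direct terminal repeat characteristic of
    headful-packaged assemblies.  Returns the genome and a truth record
    (coding density %, start/stop codon tallies, exact G+C %, repeat
    length, planted intervals).
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if terminal_repeat < 0 or 2 * terminal_repeat >= length:
        raise ValueError("terminal repeat must fit inside the genome")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(bases, size=length, p=p)

    # plant genes outside the repeat-affected ends
    lo_bound = terminal_repeat + 1      # 1-based first allowed position
    hi_bound = length - terminal_repeat # last position before the copied tail
    genes: list[GeneRecord] = []
    intervals: list[tuple[int, int]] = []
    start_counts = {"ATG": 0, "GTG": 0}
    stop_counts = {"TAA": 0, "TAG": 0, "TGA": 0}
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise ValueError(
                f"could not place {n_genes} non-overlapping genes in {length} bp"
            )
        codons = int(rng.integers(gene_length_range[0] // 3, gene_length_range[1] // 3 + 1))
        if codons < 2:
            raise ValueError("minimum gene length is 6 bp (start + stop codon)")
        span = 3 * codons
        aa = codons - 1  # protein length; stop codon is untranslated
        if hi_bound - span + 1 < lo_bound:
            raise ValueError("genome too short for requested gene lengths")
        low = int(rng.integers(lo_bound, hi_bound - span + 2))
        high = low + span - 1
        if any(low <= h and l <= high for l, h in intervals):
            continue
        start_codon = "GTG" if rng.random() < p_gtg_start else "ATG"
        stop_codon = STOP_CODONS[int(rng.integers(0, 3))]
        body = "".join(_random_codon(rng, gc) for _ in range(codons - 2))
        cds = start_codon + body + stop_codon
        strand = "+" if rng.random() < 0.5 else "-"
        planted = cds if strand == "+" else cds.translate(_COMPLEMENT)[::-1]
        seq[low - 1 : high] = list(planted)
        if strand == "+":
            rec = GeneRecord(len(genes) + 1, low, high, "+", aa)
        else:
            rec = GeneRecord(len(genes) + 1, high, low, "-", aa)
        genes.append(rec)
        intervals.append((low, high))
        start_counts[start_codon] += 1
        stop_counts[stop_codon] += 1

    if terminal_repeat > 0:
        seq[length - terminal_repeat :] = seq[:terminal_repeat]
    sequence = "".join(seq)

    coding_bp = sum(h - l + 1 for l, h in intervals)
    n_gc = sequence.count("G") + sequence.count("C")
    truth = {
        "coding_density": 100.0 * coding_bp / length,
        "start_counts": start_counts,
        "stop_counts": stop_counts,
        "gc_percent": 100.0 * n_gc / length,
        "terminal_repeat": terminal_repeat,
        "intervals": intervals,
    }
    genome = AnnotatedGenome(length=length, genes=genes, sequence=sequence)
    return genome, truth


def simulate_survival(
    ld50: float,
    hill: float,
    doses: Sequence[float],
    n_per_dose: int = 10,
    seed: int = 0,
    horizon: float = 96.0,
) -> list[SurvivalRecord]:
    """Binomial dose-response deaths with p(death) = 1 / (1 + (ld50/dose)^hill)."""
    if ld50 <= 0:
        raise ValueError("ld50 must be positive")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for dose in doses:
        p = 1.0 / (1.0 + (ld50 / dose) ** hill)
        deaths = int(rng.binomial(n_per_dose, p))
        records.append(SurvivalRecord(dose=float(dose), n=n_per_dose, deaths=deaths, horizon=horizon))
    return records
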
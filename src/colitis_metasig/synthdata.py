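"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the study's data sources:

* ``simulate_counts`` — negative-binomial RNA-seq counts (variance =
  mu + alpha * mu^2) for a control and a DSS-treated group, with a planted
  set of perturbed genes at a known |log2 fold change| (half up, half down)
  and log-normal library-size variation so normalization is exercised.
* ``simulate_biosets`` — a panel of noisy study gene lists (gene, signed FC,
  p) sharing a planted consensus signature: each planted gene appears in a
  list with a set penetrance, preserved direction and a log-normal fold
  change; non-signature genes intrude at a background noise rate with random
  direction.
* ``simulate_beam_stream`` — an open-field beam-break session as a marked
  Poisson stream of rear / ambulation / fine-movement episodes over a beam
  grid, returned together with the exact metric panel implied by the drawn
  events.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .metasig import Bioset, OrthologMap
from .openfield import Apparatus, BeamEventStream

__all__ = [
    "CountSimConfig",
    "BiosetSimConfig",
    "FcDist",
    "BeamSimConfig",
    "simulate_counts",
    "simulate_biosets",
    "simulate_beam_stream",
    "simulate_ortholog_map",
]


@dataclasses.dataclass
class CountSimConfig:
    """Study conditions for the RNA-seq count generator.

    Defaults model a desk-scale two-group colon RNA-seq experiment:
    5 animals per cage and per group, 1000 expressed genes of which 100 are
    perturbed by DSS at |log2 FC| = 1.5, NB dispersion 0.2, mean expression
    log-normal around exp(5.5) ~ 245 reads, and ~30% library-size variation.
    """

    n_genes: int = 1000
    n_per_group: int = 5
    baseline_log_mean: float = 5.5  # natural-log scale of mean expression
    baseline_log_sd: float = 1.0
    dispersion: float = 0.2  # alpha in var = mu + alpha * mu^2
    n_perturbed: int = 100
    lfc_magnitude: float = 1.5  # planted |log2 FC|
    library_size_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ValueError("n_genes and n_per_group must be positive")
        if self.n_perturbed > self.n_genes or self.n_perturbed < 0:
            raise ValueError("n_perturbed must lie in [0, n_genes]")
        if min(self.dispersion, self.lfc_magnitude, self.library_size_cv, self.baseline_log_sd) < 0:
            raise ValueError("scale parameters must be >= 0")


def _lognormal_depth(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Relative sequencing depths with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=n)


def simulate_counts(cfg: CountSimConfig) -> tuple[CountMatrix, dict[str, str]]:
    """Draw a control/DSS count matrix; returns (matrix, truth).

    ``truth`` maps each planted gene id to its direction ("up"/"down") in
    the treated group relative to control; the expected treated/control mean
    ratio of a planted gene is 2**lfc_magnitude (or its inverse).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"mg{i:05d}" for i in range(cfg.n_genes)]
    mu = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))

    perturbed_idx = rng.choice(cfg.n_genes, size=cfg.n_perturbed, replace=False)
    signs = np.zeros(cfg.n_genes)
    half = cfg.n_perturbed // 2
    signs[perturbed_idx[:half]] = 1.0  # up in treated
    signs[perturbed_idx[half:]] = -1.0
    fc = 2.0 ** (cfg.lfc_magnitude * signs)

    n = cfg.n_per_group
    samples = [f"ctrl_{i+1}" for i in range(n)] + [f"dss_{i+1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["dss"] * n, index=samples)
    depth = _lognormal_depth(rng, 2 * n, cfg.library_size_cv)

    mean_mat = np.empty((cfg.n_genes, 2 * n))
    mean_mat[:, :n] = mu[:, None] * depth[None, :n]
    mean_mat[:, n:] = (mu * fc)[:, None] * depth[None, n:]

    if cfg.dispersion == 0:
        counts = rng.poisson(mean_mat)
    else:
        r = 1.0 / cfg.dispersion
        p = r / (r + mean_mat)
        counts = rng.negative_binomial(r, p)

    m = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), groups=groups)
    truth = {
        genes[i]: ("up" if signs[i] > 0 else "down")
        for i in perturbed_idx
    }
    return m, truth


@dataclasses.dataclass
class FcDist:
    """Log-normal fold-change magnitude: mean ``mean_fc``, log-scale sd
    ``sigma_log``, truncated below at ``min_fc``."""

    mean_fc: float = 2.5
    sigma_log: float = 0.2
    min_fc: float = 1.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu_log = math.log(self.mean_fc) - self.sigma_log**2 / 2
        return np.maximum(rng.lognormal(mu_log, self.sigma_log, size), self.min_fc)


@dataclasses.dataclass
class BiosetSimConfig:
    """Conditions for the multi-study gene-list panel.

    Defaults mirror an 18-list panel over a 500-gene universe with a
    50-gene planted signature; penetrance 0.7 puts the expected vote count
    at ~12 of 18 for signature genes, and a 2% background noise rate plants
    sporadic false perturbations.
    """

    n_lists: int = 18
    n_genes_universe: int = 500
    planted_signature: dict[str, str] | None = None  # gene -> "up"/"down"
    n_signature: int = 50  # used when planted_signature is None
    planted_penetrance: float = 0.7
    fc_magnitude_dist: FcDist = dataclasses.field(default_factory=FcDist)
    noise_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_universe <= 0:
            raise ValueError("empty gene universe")
        if not (0 <= self.planted_penetrance <= 1 and 0 <= self.noise_rate <= 1):
            raise ValueError("penetrance and noise_rate must lie in [0, 1]")

    @property
    def universe(self) -> list[str]:
        return [f"hs{i:05d}" for i in range(self.n_genes_universe)]

    def signature(self) -> dict[str, str]:
        if self.planted_signature is not None:
            bad = set(self.planted_signature) - set(self.universe)
            if bad:
                raise ValueError(f"planted signature outside universe: {sorted(bad)}")
            return dict(self.planted_signature)
        if self.n_signature > self.n_genes_universe:
            raise ValueError("n_signature exceeds universe size")
        return {
            f"hs{i:05d}": ("up" if i % 2 == 0 else "down")
            for i in range(self.n_signature)
        }


def simulate_biosets(cfg: BiosetSimConfig) -> tuple[list[Bioset], dict[str, str]]:
    """Draw the noisy study-list panel; returns (biosets, truth signature).

    Planted genes enter a list with probability ``planted_penetrance``,
    keeping their direction, |FC| from ``fc_magnitude_dist`` and a strongly
    significant p-value (10**-U(1.5, 6)); noise genes enter with probability
    ``noise_rate``, random direction and p ~ U(0, 0.05).
    """
    rng = np.random.default_rng(cfg.seed)
    signature = cfg.signature()
    sig_genes = sorted(signature)
    noise_pool = [g for g in cfg.universe if g not in signature]

    biosets = []
    for j in range(cfg.n_lists):
        genes: list[str] = []
        fcs: list[float] = []
        ps: list[float] = []

        hit = rng.random(len(sig_genes)) < cfg.planted_penetrance
        n_hit = int(hit.sum())
        mags = cfg.fc_magnitude_dist.draw(rng, n_hit)
        pvals = 10.0 ** -rng.uniform(1.5, 6.0, n_hit)
        k = 0
        for g, h in zip(sig_genes, hit):
            if h:
                sign = 1.0 if signature[g] == "up" else -1.0
                genes.append(g)
                fcs.append(sign * mags[k])
                ps.append(pvals[k])
                k += 1

        noise_hit = rng.random(len(noise_pool)) < cfg.noise_rate
        n_noise = int(noise_hit.sum())
        noise_mags = cfg.fc_magnitude_dist.draw(rng, n_noise)
        noise_signs = rng.choice([-1.0, 1.0], size=n_noise)
        noise_ps = rng.uniform(0.0, 0.05, n_noise)
        k = 0
        for g, h in zip(noise_pool, noise_hit):
            if h:
                genes.append(g)
                fcs.append(noise_signs[k] * noise_mags[k])
                ps.append(noise_ps[k])
                k += 1

        biosets.append(
            Bioset(f"study_{j+1:02d}", pd.DataFrame({"gene": genes, "fc": fcs, "p": ps}))
        )
    return biosets, signature


@dataclasses.dataclass
class BeamSimConfig:
    """Conditions for one open-field session.

    Rates are per minute; a 60-minute session with ~2 rears/min of ~1.5 s,
    ~20 ambulation steps/min and ~10 fine movements/min approximates a
    healthy exploring mouse. Event arrivals form a marked Poisson process
    (inter-event pauses are exponential with rate equal to the summed event
    rates); episode durations are truncated normal for rears and a fixed
    short break for horizontal events.
    """

    session_length: float = 3600.0
    rear_rate: float = 2.0  # rears / min
    rear_duration_mean: float = 1.5  # s
    rear_duration_sd: float = 0.5
    ambulation_rate: float = 20.0  # relocation steps / min
    fine_rate: float = 10.0  # in-place horizontal breaks / min
    event_duration: float = 0.1  # s, horizontal beam-break duration
    beam_pitch: float = 2.54
    n_beams_x: int = 16
    n_beams_y: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")
        if min(self.rear_rate, self.ambulation_rate, self.fine_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.rear_duration_mean <= 0 or self.rear_duration_sd < 0:
            raise ValueError("rear durations must be positive")


def _truth_panel(
    events: pd.DataFrame,
    session_length: float,
    n_ambulation: int,
    n_fine: int,
    total_steps: int,
    beam_pitch: float,
    rest_threshold: float,
) -> dict[str, float]:
    """Exact metric panel implied by a drawn event list (generator-side scan)."""
    vert = events[events["kind"] == "vertical"]
    rearing_time = float(sum(t1 - t0 for t0, t1 in zip(vert["t_start"], vert["t_end"])))

    # merge-scan over all break intervals for immobility and rest gaps
    merged: list[tuple[float, float]] = []
    for t0, t1 in zip(events["t_start"], events["t_end"]):
        if merged and t0 <= merged[-1][1]:
            if t1 > merged[-1][1]:
                merged[-1] = (merged[-1][0], t1)
        else:
            merged.append((t0, t1))
    active = float(sum(t1 - t0 for t0, t1 in merged))
    gaps: list[tuple[float, float]] = []
    cursor = 0.0
    for t0, t1 in merged:
        if t0 > cursor:
            gaps.append((cursor, t0))
        cursor = max(cursor, t1)
    if cursor < session_length:
        gaps.append((cursor, session_length))
    rest = float(sum(g1 - g0 for g0, g1 in gaps if g1 - g0 > rest_threshold))

    n_rears = int(len(vert))
    n_horiz = int((events["kind"] == "horizontal").sum())
    return {
        "basic_movements": float(n_horiz),
        "fine_movements": float(n_fine),
        "xy_ambulation": float(n_ambulation),
        "rears": float(n_rears),
        "rearing_time": rearing_time,
        "immobility_time": session_length - active,
        "rest_time": rest,
        "distance": beam_pitch * total_steps,
        "normalized_rears": (n_rears / n_ambulation) if n_ambulation else float("nan"),
        "avg_rear_duration": (rearing_time / n_rears) if n_rears else float("nan"),
    }


def simulate_beam_stream(
    cfg: BeamSimConfig, animal_id: str = "animal", rest_threshold: float = 15.0
) -> tuple[BeamEventStream, dict[str, float]]:
    """Draw one session and its exact ground-truth metric panel.

    The animal starts at the center beam position; each ambulation episode
    moves it by exactly one beam index (city block), fine movements break the
    beam in place, rears break the vertical array for a truncated-normal
    duration. Episodes never overlap: arrivals falling within (or within
    1 ms after) an active episode are dropped, thinning the nominal rates
    slightly by the busy fraction of the session.
    """
    rng = np.random.default_rng(cfg.seed)
    ap = Apparatus(cfg.beam_pitch, cfg.n_beams_x, cfg.n_beams_y)

    rates = np.array([cfg.rear_rate, cfg.ambulation_rate, cfg.fine_rate]) / 60.0
    lam = rates.sum()
    arrivals: list[tuple[float, int]] = []
    if lam > 0:
        t = 0.0
        probs = rates / lam
        while True:
            t += rng.exponential(1.0 / lam)
            if t >= cfg.session_length:
                break
            arrivals.append((t, int(rng.choice(3, p=probs))))

    pos = ap.start_position
    rows = []
    n_ambulation = n_fine = total_steps = 0
    for t0, kind in arrivals:
        if rows and t0 - rows[-1][1] < 1e-3:
            continue  # previous episode still (or just) active; drop the arrival
        if kind == 0:
            dur = max(0.1, rng.normal(cfg.rear_duration_mean, cfg.rear_duration_sd))
            t1 = min(t0 + dur, cfg.session_length)
            if t1 - t0 < 1e-6:
                continue
            rows.append((t0, t1, "vertical", pos[0], pos[1]))
        else:
            t1 = min(t0 + cfg.event_duration, cfg.session_length)
            if t1 - t0 < 1e-6:
                continue
            if kind == 1:
                # relocate by one beam index along a uniformly chosen valid axis step
                moves = []
                if pos[0] > 0:
                    moves.append((-1, 0))
                if pos[0] < ap.n_beams_x - 1:
                    moves.append((1, 0))
                if pos[1] > 0:
                    moves.append((0, -1))
                if pos[1] < ap.n_beams_y - 1:
                    moves.append((0, 1))
                dx, dy = moves[rng.integers(len(moves))]
                pos = (pos[0] + dx, pos[1] + dy)
                n_ambulation += 1
                total_steps += 1
            else:
                n_fine += 1
            rows.append((t0, t1, "horizontal", pos[0], pos[1]))

    events = pd.DataFrame(
        rows, columns=["t_start", "t_end", "kind", "beam_x", "beam_y"]
    )
    stream = BeamEventStream(animal_id, cfg.session_length, events, ap)
    truth = _truth_panel(
        events,
        cfg.session_length,
        n_ambulation,
        n_fine,
        total_steps,
        cfg.beam_pitch,
        rest_threshold,
    )
    return stream, truth


def simulate_ortholog_map(
    source_genes: list[str],
    mapped_fraction: float = 0.85,
    seed: int = 0,
    target_format: str = "hs{i:05d}",
) -> OrthologMap:
    """Partial one-to-one ortholog map: a random ``mapped_fraction`` of
    source genes map to target ids by index; the rest are unmapped."""
    if not 0 <= mapped_fraction <= 1:
        raise ValueError("mapped_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(source_genes)
    n_mapped = int(round(mapped_fraction * n))
    idx = np.sort(rng.choice(n, size=n_mapped, replace=False))
    pairs = pd.DataFrame(
        {
            "source": [source_genes[i] for i in idx],
            "target": [target_format.format(i=i) for i in idx],
        }
    )
    return OrthologMap(pairs)
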
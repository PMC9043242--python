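"""Synthetic EEG generation: patch sources, AR(5) dynamics, SNR control.

Each trial activates one or more source *patches* — a center vertex plus its
level-1 mesh neighbors, the neighbors at reduced amplitude — carrying a
shared temporal waveform drawn from a stable 5th-order autoregressive
process.  The clean EEG is the forward projection through the lead field;
sensor noise is white Gaussian scaled so the realized signal-to-noise ratio
``10*log10(P_signal / P_noise)`` (powers = mean square over all channels and
samples) hits the requested value exactly.

Trials are split 70/15/15 into train/validation/test by default, with
largest-remainder rounding of the split sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .source_space import LeadField, SourceGraph, SourceSpace

__all__ = [
    "PatchSpec",
    "SimSample",
    "Dataset",
    "default_ar_coefficients",
    "ar_waveform",
    "sample_patches",
    "render_sources",
    "add_noise_snr",
    "split_sizes",
    "make_dataset",
]

#: default train/validation/test fractions
DEFAULT_SPLIT = (0.70, 0.15, 0.15)

#: default relative amplitude of a patch's neighbor vertices vs. its center
DEFAULT_NEIGHBOR_SCALE = 0.5


def default_ar_coefficients() -> np.ndarray:
    """Stable AR(5) coefficients used for source waveforms.

    Built from fixed poles — a lightly damped alpha-band pair
    ``0.95*exp(+-2i*pi*0.10)``, a faster damped pair
    ``0.90*exp(+-2i*pi*0.20)`` and one real pole at 0.6 — giving a
    spectral radius of 0.95 (stationary but temporally correlated, with
    oscillatory structure at 10 and 20 Hz when sampled at 100 Hz).
    """
    poles = np.array(
        [
            0.95 * np.exp(2j * np.pi * 0.10),
            0.95 * np.exp(-2j * np.pi * 0.10),
            0.90 * np.exp(2j * np.pi * 0.20),
            0.90 * np.exp(-2j * np.pi * 0.20),
            0.60,
        ]
    )
    # monic polynomial z^5 + c1 z^4 + ... + c5 with these roots; the AR
    # recursion coefficients are the negated non-leading coefficients
    return -np.real(np.poly(poles))[1:]


def ar_stability_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the AR companion matrix (< 1 means stable)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p = len(coeffs)
    companion = np.zeros((p, p))
    companion[0, :] = coeffs
    companion[1:, :-1] = np.eye(p - 1)
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def ar_waveform(
    T: int,
    fs_hz: float = 100.0,
    coeffs: np.ndarray | None = None,
    noise_sd: float = 1.0,
    rng_seed: int | np.random.SeedSequence = 0,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate ``T`` samples of a stable AR process, zero-initialized with
    a discarded burn-in.

    ``fs_hz`` is carried for bookkeeping (the recursion itself is sample
    indexed).  Raises if the coefficients are unstable, naming the
    companion-matrix spectral radius.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if burn_in < 200:
        burn_in = 200
    if coeffs is None:
        coeffs = default_ar_coefficients()
    coeffs = np.asarray(coeffs, dtype=float)
    radius = ar_stability_radius(coeffs)
    if radius >= 1.0:
        raise ValueError(
            f"AR coefficients are unstable (companion spectral radius "
            f"{radius:.4f} >= 1)"
        )
    rng = np.random.default_rng(rng_seed)
    innovations = rng.normal(0.0, noise_sd, size=burn_in + T)
    # s_t - sum_i a_i s_{t-i} = e_t  <=>  all-pole filter with zero state
    out = scipy.signal.lfilter([1.0], np.concatenate([[1.0], -coeffs]), innovations)
    return out[burn_in:]


@dataclass
class PatchSpec:
    """One or more disjoint source patches: centers plus level-1 members."""

    centers: list[int]
    members: list[np.ndarray]  # per patch: center + its neighbors
    neighbor_scale: float = DEFAULT_NEIGHBOR_SCALE

    def __post_init__(self) -> None:
        if not 0 < self.neighbor_scale <= 1:
            raise ValueError("neighbor_scale must be in (0, 1]")
        for c, mem in zip(self.centers, self.members):
            if c not in mem:
                raise ValueError("each member set must contain its center")
        all_members = np.concatenate(self.members) if self.members else np.array([])
        if len(np.unique(all_members)) != len(all_members):
            raise ValueError("patches share vertices")

    @property
    def all_members(self) -> np.ndarray:
        return np.unique(np.concatenate(self.members))

    def active_mask(self, m: int) -> np.ndarray:
        mask = np.zeros(m, dtype=bool)
        mask[self.all_members.astype(int)] = True
        return mask


@dataclass
class SimSample:
    """One simulated trial."""

    s_true: np.ndarray  # (m, T)
    x_clean: np.ndarray  # (n, T)
    x_noisy: np.ndarray  # (n, T)
    patch: PatchSpec
    snr_db: float
    fs_hz: float
    seed: int


@dataclass
class Dataset:
    """Simulated trials plus disjoint train/val/test index sets."""

    samples: list[SimSample]
    split: dict[str, np.ndarray]  # keys train/val/test, values index arrays
    config: dict = field(default_factory=dict)

    def subset(self, name: str) -> list[SimSample]:
        return [self.samples[i] for i in self.split[name]]


def sample_patches(
    graph: SourceGraph,
    n_patches: int,
    rng_seed: int | np.random.Generator = 0,
    neighbor_scale: float = DEFAULT_NEIGHBOR_SCALE,
    max_retries: int = 200,
) -> PatchSpec:
    """Draw ``n_patches`` vertex-disjoint patches: centers uniform without
    replacement, members = center plus direct mesh neighbors; resampled
    until disjoint (bounded retries)."""
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    m = graph.m
    for _ in range(max_retries):
        centers = rng.choice(m, size=n_patches, replace=False)
        members = [
            np.unique(np.append(graph.neighbors(int(c)), int(c))) for c in centers
        ]
        total = sum(len(mem) for mem in members)
        if len(np.unique(np.concatenate(members))) == total:
            return PatchSpec(
                centers=[int(c) for c in centers],
                members=members,
                neighbor_scale=neighbor_scale,
            )
    raise RuntimeError(
        f"could not draw {n_patches} disjoint patches in {max_retries} tries"
    )


def render_sources(
    space: SourceSpace | int,
    patch: PatchSpec,
    waveforms: list[np.ndarray],
    neighbor_scale: float | None = None,
) -> np.ndarray:
    """Place one waveform per patch on the mesh: the center at scale 1,
    level-1 members at ``neighbor_scale``, all other vertices exactly zero.

    Returns the (m, T) source movie.
    """
    m = space if isinstance(space, int) else space.m
    scale = patch.neighbor_scale if neighbor_scale is None else neighbor_scale
    if not 0 < scale <= 1:
        raise ValueError("neighbor_scale must be in (0, 1]")
    if len(waveforms) != len(patch.centers):
        raise ValueError("need exactly one waveform per patch")
    T = len(waveforms[0])
    s = np.zeros((m, T))
    for center, mem, w in zip(patch.centers, patch.members, waveforms):
        w = np.asarray(w, dtype=float)
        s[mem, :] = scale * w[None, :]
        s[center, :] = w
    return s


def add_noise_snr(
    x_clean: np.ndarray,
    snr_db: float,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add white Gaussian sensor noise rescaled so the realized SNR (dB)
    equals ``snr_db`` exactly, powers taken as mean square over all channels
    and samples jointly."""
    x_clean = np.asarray(x_clean, dtype=float)
    p_signal = np.mean(x_clean**2)
    if p_signal == 0:
        raise ValueError("x_clean has zero power; SNR is undefined")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    noise = rng.standard_normal(x_clean.shape)
    p_target = p_signal / 10.0 ** (snr_db / 10.0)
    noise *= np.sqrt(p_target / np.mean(noise**2))
    return x_clean + noise


def split_sizes(n: int, fractions: tuple[float, ...] = DEFAULT_SPLIT) -> list[int]:
    """Largest-remainder apportionment of ``n`` items to the fractions."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    exact = fractions * n
    sizes = np.floor(exact).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(exact - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    return sizes.tolist()


def make_dataset(
    space: SourceSpace,
    graph: SourceGraph,
    leadfield: LeadField,
    snr_db: float,
    n_samples: int | None = None,
    n_patches: int = 1,
    fractions: tuple[float, float, float] = DEFAULT_SPLIT,
    seed: int = 0,
    T: int = 100,
    fs_hz: float = 100.0,
    neighbor_scale: float = DEFAULT_NEIGHBOR_SCALE,
    ar_coeffs: np.ndarray | None = None,
) -> Dataset:
    """Generate a simulated dataset.

    Single-patch mode (``n_patches=1``): every vertex serves as a patch
    center in turn; ``n_samples`` smaller than ``m`` selects a seeded
    subsample of centers for scaled-down runs.  Multi-patch mode: each trial
    draws ``n_patches`` random disjoint patches.
    """
    m = space.m
    ss = np.random.SeedSequence(seed)
    split_ss, *_ = ss.spawn(1)
    rng = np.random.default_rng(ss)

    if n_patches == 1:
        if n_samples is None or n_samples == m:
            centers = np.arange(m)
        elif n_samples < m:
            centers = rng.choice(m, size=n_samples, replace=False)
        else:
            raise ValueError(
                f"single-patch mode enumerates centers; n_samples={n_samples} "
                f"cannot exceed m={m}"
            )
        patches = [
            PatchSpec(
                centers=[int(c)],
                members=[np.unique(np.append(graph.neighbors(int(c)), int(c)))],
                neighbor_scale=neighbor_scale,
            )
            for c in centers
        ]
    else:
        if n_samples is None:
            raise ValueError("n_samples is required for multi-patch mode")
        patches = [
            sample_patches(graph, n_patches, rng, neighbor_scale=neighbor_scale)
            for _ in range(n_samples)
        ]

    n_total = len(patches)
    sizes = split_sizes(n_total, fractions)
    if min(sizes) < 1:
        raise ValueError(f"{n_total} samples cannot fill splits {fractions}")

    samples: list[SimSample] = []
    for idx, patch in enumerate(patches):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(1, idx))
        wave_rng, noise_rng = [np.random.default_rng(c) for c in child.spawn(2)]
        waves = [
            ar_waveform(T, fs_hz=fs_hz, coeffs=ar_coeffs, rng_seed=wave_rng)
            for _ in patch.centers
        ]
        s_true = render_sources(m, patch, waves)
        x_clean = leadfield.gain @ s_true
        x_noisy = add_noise_snr(x_clean, snr_db, noise_rng)
        samples.append(
            SimSample(
                s_true=s_true,
                x_clean=x_clean,
                x_noisy=x_noisy,
                patch=patch,
                snr_db=snr_db,
                fs_hz=fs_hz,
                seed=idx,
            )
        )

    perm = np.random.default_rng(split_ss).permutation(n_total)
    split = {
        "train": np.sort(perm[: sizes[0]]),
        "val": np.sort(perm[sizes[0] : sizes[0] + sizes[1]]),
        "test": np.sort(perm[sizes[0] + sizes[1] :]),
    }
    config = {
        "m": m,
        "n": leadfield.n,
        "snr_db": snr_db,
        "n_samples": n_total,
        "n_patches": n_patches,
        "fractions": list(fractions),
        "seed": seed,
        "T": T,
        "fs_hz": fs_hz,
        "neighbor_scale": neighbor_scale,
    }
    return Dataset(samples=samples, split=split, config=config)
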
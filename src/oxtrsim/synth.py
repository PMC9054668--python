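"""Seeded generators for every input the pipeline consumes offline.

* imaging-like Ca2+ traces (bi-exponential transient, drift, noise,
  lognormal per-cell amplitudes) with a per-cell ground-truth table,
* differential-expression + gene-category tables with planted regulated
  genes and planted per-category overlaps,
* ideal alpha-helix coordinate fixtures (single helix or a two-helix
  "dimer") in fixed-column PDB text.

All generators are pure functions of their spec; the seed is part of the
spec, so identical specs give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import AtomRecord, write_pdb
from .crossref import bh_adjust
from .metrics import CaTrace

# ---------------------------------------------------------------------------
# Ca2+ traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceGenSpec:
    n_cells: int = 50
    sampling_dt: float = 0.5  # s
    t_total: float = 300.0
    t_stim: float = 60.0
    baseline_mean: float = 0.8  # fura2-ratio-like units
    baseline_cv: float = 0.05
    amplitude_mean: float = 0.5
    amplitude_sigma: float = 0.2  # lognormal log-sd
    rise_tau: float = 3.0
    decay_tau: float = 25.0
    drift_slope: float = 0.0  # signal units / s
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.sampling_dt <= 0 or self.t_total <= 0:
            raise ValueError("n_cells, sampling_dt and t_total must be positive")
        if not (0 <= self.t_stim < self.t_total):
            raise ValueError("t_stim must lie in [0, t_total)")
        if self.rise_tau <= 0 or self.decay_tau <= self.rise_tau:
            raise ValueError("require 0 < rise_tau < decay_tau")
        if self.amplitude_mean < 0 or self.noise_sd < 0 or self.baseline_cv < 0:
            raise ValueError("amplitude_mean, noise_sd, baseline_cv must be >= 0")


def pulse_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Bi-exponential pulse normalized to unit peak; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(
        decay_tau / rise_tau
    )
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    out = np.where(
        t >= 0,
        np.exp(-np.clip(t, 0, None) / decay_tau)
        - np.exp(-np.clip(t, 0, None) / rise_tau),
        0.0,
    )
    return out / norm


def pulse_fwhm(rise_tau: float, decay_tau: float) -> float:
    """FWHM of the unit-peak bi-exponential pulse, root-solved numerically."""
    from scipy.optimize import brentq

    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(
        decay_tau / rise_tau
    )

    def f(t):
        return float(pulse_kernel(np.array([t]), rise_tau, decay_tau)[0]) - 0.5

    t_up = brentq(f, 0.0, t_peak)
    hi = t_peak
    while f(hi) > 0:
        hi *= 2.0
    t_down = brentq(f, t_peak, hi)
    return t_down - t_up


def synth_traces(spec: TraceGenSpec) -> tuple[list[CaTrace], pd.DataFrame]:
    """Generate n_cells traces and the per-cell ground-truth table.

    signal = baseline + drift*t + A * kernel(t - t_stim) + N(0, noise_sd),
    with per-cell baseline ~ baseline_mean*(1 + CV*z) and per-cell A
    lognormal with mean exactly amplitude_mean (log-sd amplitude_sigma).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_total + spec.sampling_dt / 2, spec.sampling_dt)
    kernel = pulse_kernel(t - spec.t_stim, spec.rise_tau, spec.decay_tau)

    traces, truth_rows = [], []
    for c in range(spec.n_cells):
        baseline = spec.baseline_mean * (1.0 + spec.baseline_cv * rng.standard_normal())
        baseline = max(baseline, 0.0)
        if spec.amplitude_mean > 0:
            mu = math.log(spec.amplitude_mean) - spec.amplitude_sigma**2 / 2
            amp = float(rng.lognormal(mean=mu, sigma=spec.amplitude_sigma))
        else:
            amp = 0.0
        noise = spec.noise_sd * rng.standard_normal(t.size)
        signal = baseline + spec.drift_slope * t + amp * kernel + noise
        cell_id = f"cell{c:03d}"
        traces.append(CaTrace(
            time=t.copy(), signal=signal, signal_kind="fura2_ratio",
            cell_id=cell_id, t_stim=spec.t_stim,
        ))
        truth_rows.append({"cell_id": cell_id, "baseline": baseline,
                           "amplitude": amp})
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# DE + gene-category tables
# ---------------------------------------------------------------------------

#: shape of the Beta(a, 1) alternative p-value distribution for planted
#: regulated genes; mass is piled near 0 so permissive thresholds recover
#: the planted set exactly.
ALT_P_BETA_A = 0.01


@dataclass(frozen=True)
class TableGenSpec:
    n_genes: int = 2000
    frac_de: float = 0.1
    lfc_effect_mean: float = 2.5  # planted minimum |log2fc| for DE genes
    lfc_effect_sd: float = 0.5
    n_sfari: int = 100
    planted_overlap: dict = field(default_factory=lambda: {"1": 5, "2": 3, "3": 2})
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or not (0.0 <= self.frac_de <= 1.0):
            raise ValueError("need n_genes >= 1 and frac_de in [0, 1]")
        n_de = round(self.n_genes * self.frac_de)
        if sum(self.planted_overlap.values()) > min(n_de, self.n_sfari):
            raise ValueError(
                "planted overlap exceeds min(planted DE genes, n_sfari)"
            )


def synth_de_tables(
    spec: TableGenSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """DE table, gene-category table and the planted ground truth.

    Null genes: log2fc ~ N(0, 0.2), p ~ U(0, 1).  Planted DE genes:
    |log2fc| = effect_mean + |N(0, effect_sd)| with random sign and
    p ~ Beta(0.01, 1).  The category table contains the planted per-
    category overlap genes (drawn from the planted DE genes) plus filler
    genes absent from the DE table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n_de = round(n * spec.frac_de)
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True

    log2fc = rng.normal(0.0, 0.2, size=n)
    pvals = rng.uniform(0.0, 1.0, size=n)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    log2fc[de_idx] = signs * (
        spec.lfc_effect_mean + np.abs(rng.normal(0.0, spec.lfc_effect_sd, n_de))
    )
    pvals[de_idx] = rng.beta(ALT_P_BETA_A, 1.0, size=n_de)
    padj = bh_adjust(pvals)
    de_table = pd.DataFrame({
        "gene_id": gene_ids, "log2fc": log2fc, "pvalue": pvals, "padj": padj,
    })

    cats, counts = zip(*sorted(spec.planted_overlap.items())) if spec.planted_overlap \
        else ((), ())
    n_overlap = int(sum(counts))
    overlap_genes = rng.choice(gene_ids[de_idx], size=n_overlap, replace=False) \
        if n_overlap else np.array([], dtype=object)
    sfari_rows = []
    pos = 0
    truth_overlap: dict[str, list[str]] = {}
    for cat, k in zip(cats, counts):
        chosen = [str(g) for g in overlap_genes[pos:pos + k]]
        pos += k
        truth_overlap[str(cat)] = sorted(chosen)
        for g in chosen:
            sfari_rows.append({"gene_id": g, "category": str(cat),
                               "n_reports": int(rng.integers(1, 60))})
    filler_cats = [c for c in ("1", "2", "3") for _ in range(3)] or ["1"]
    for j in range(spec.n_sfari - n_overlap):
        sfari_rows.append({
            "gene_id": f"ASDX{j:04d}",  # namespace disjoint from the DE table
            "category": filler_cats[j % len(filler_cats)],
            "n_reports": int(rng.integers(1, 60)),
        })
    sfari_table = pd.DataFrame(sfari_rows,
                               columns=["gene_id", "category", "n_reports"])
    truth = {
        "de_genes": sorted(str(g) for g in gene_ids[de_idx]),
        "overlap": truth_overlap,
    }
    return de_table, sfari_table, truth


# ---------------------------------------------------------------------------
# Ideal-helix coordinate fixtures
# ---------------------------------------------------------------------------

ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "T": "THR",
    "V": "VAL", "L": "LEU", "I": "ILE",
}

CA_RADIUS = 2.3  # A, ideal alpha-helix C-alpha radius
# tilt toward the N-terminus; 40 deg puts bulky side chains of i+-3/i+-4
# (one helix turn) inside a 5.5 A cutoff while keeping i+-1 outside it
SIDECHAIN_TILT = math.radians(40.0)


def _helix_point(s: float, radius: float, theta0: float, twist: float,
                 rise: float) -> np.ndarray:
    th = theta0 + s * twist
    return np.array([radius * math.cos(th), radius * math.sin(th), s * rise])


def _sidechain_frame(theta: float) -> tuple[np.ndarray, np.ndarray]:
    """(direction, perpendicular) for side chains: radially outward, tilted
    toward the helix N-terminus so i/i+-3,4 side chains approach."""
    radial = np.array([math.cos(theta), math.sin(theta), 0.0])
    d = math.cos(SIDECHAIN_TILT) * radial - math.sin(SIDECHAIN_TILT) * np.array(
        [0.0, 0.0, 1.0]
    )
    perp = np.array([-math.sin(theta), math.cos(theta), 0.0])
    return d, perp


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sidechain_atoms(resname: str, ca: np.ndarray, d: np.ndarray,
                     perp: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """(atom_name, element, position) side-chain templates."""
    if resname == "GLY":
        return []
    cb = ca + 1.53 * d
    out = [("CB", "C", cb)]
    if resname == "ALA":
        return out
    if resname == "SER":
        out.append(("OG", "O", cb + 1.43 * d))
    elif resname == "THR":
        out.append(("OG1", "O", cb + 1.43 * _unit(d + 0.55 * perp)))
        out.append(("CG2", "C", cb + 1.52 * _unit(d - 0.55 * perp)))
    elif resname == "VAL":
        out.append(("CG1", "C", cb + 1.53 * _unit(d + 0.55 * perp)))
        out.append(("CG2", "C", cb + 1.53 * _unit(d - 0.55 * perp)))
    elif resname == "LEU":
        cg = cb + 1.53 * d
        out.append(("CG", "C", cg))
        out.append(("CD1", "C", cg + 1.53 * _unit(d + 0.45 * perp)))
        out.append(("CD2", "C", cg + 1.53 * _unit(d - 0.45 * perp)))
    elif resname == "ILE":
        cg1 = cb + 1.53 * _unit(d + 0.45 * perp)
        out.append(("CG1", "C", cg1))
        out.append(("CG2", "C", cb + 1.53 * _unit(d - 0.45 * perp)))
        out.append(("CD1", "C", cg1 + 1.53 * d))
    else:
        raise ValueError(f"unsupported residue code {resname!r}")
    return out


def synth_helix_pdb(
    n_res: int = 15,
    residue_pattern: str = "L",
    rise: float = 1.5,
    twist_deg: float = 100.0,
    chains: int = 1,
    axis_sep: float = 10.0,
    facing: bool = True,
) -> str:
    """Fixed-column PDB text for an ideal helix (or a two-helix dimer).

    The residue pattern (one-letter codes) is cycled to n_res residues.
    The central residue's side chain points along +x for chain A; with
    ``facing=True`` chain B (translated +x by axis_sep) is rotated so its
    central residue points back along -x.
    """
    if n_res < 7:
        raise ValueError("need n_res >= 7 for a meaningful helix")
    if chains not in (1, 2):
        raise ValueError("chains must be 1 or 2")
    seq = [residue_pattern[i % len(residue_pattern)].upper() for i in range(n_res)]
    bad = sorted({c for c in seq if c not in ONE_TO_THREE})
    if bad:
        raise ValueError(f"unknown residue code(s) {bad}; supported: "
                         f"{sorted(ONE_TO_THREE)}")
    twist = math.radians(twist_deg)
    center = n_res // 2  # 0-based index of the central residue

    atoms: list[AtomRecord] = []
    serial = 1

    def emit_chain(chain_id: str, theta0: float, x_shift: float):
        nonlocal serial
        for i, code in enumerate(seq):
            resname = ONE_TO_THREE[code]
            theta = theta0 + i * twist
            ca = _helix_point(i, CA_RADIUS, theta0, twist, rise)
            n_pos = _helix_point(i - 0.35, 1.8, theta0, twist, rise)
            c_pos = _helix_point(i + 0.35, 1.8, theta0, twist, rise)
            o_pos = c_pos + np.array([0.0, 0.0, -0.6]) + 0.6 * _unit(
                np.array([-c_pos[0], -c_pos[1], 0.0])
            )
            d, perp = _sidechain_frame(theta)
            placed = [("N", "N", n_pos), ("CA", "C", ca), ("C", "C", c_pos),
                      ("O", "O", o_pos)]
            placed += _sidechain_atoms(resname, ca, d, perp)
            for name, elem, pos in placed:
                atoms.append(AtomRecord(
                    serial=serial, atom_name=name, alt_loc="",
                    residue_name=resname, chain_id=chain_id,
                    residue_number=i + 1,
                    xyz=(round(pos[0] + x_shift, 3), round(pos[1], 3),
                         round(pos[2], 3)),
                    occupancy=1.0, element=elem,
                ))
                serial += 1

    theta0_a = -center * twist  # central residue faces +x
    emit_chain("A", theta0_a, 0.0)
    if chains == 2:
        theta0_b = theta0_a + (math.pi if facing else 0.0)
        emit_chain("B", theta0_b, axis_sep)
    return write_pdb(atoms)
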
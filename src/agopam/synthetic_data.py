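"""Ground-truth generators for every input the analysis pipeline consumes.

Four generators, all fully deterministic under a fixed seed (numpy
``default_rng``, PCG64):

* mutant panels — replicate-level dose-response tables and construct
  records driven by the two-state activation model, with construct-specific
  constitutive activity and multiplicative log-normal noise;
* potentiation curve families — orthosteric-agonist 4PL curves whose EC50
  shifts left and Emax scales with modulator concentration
  (phenomenological on purpose, so that pipeline recovery tests are not
  circular with the mechanistic model);
* kinetic traces — flat baseline followed by a single-exponential approach,
  plus additive Gaussian noise;
* geometry fixtures — a hollow-shell pseudo-protein with an analytically
  known cavity volume, a small rigid pseudo-ligand, and rigidly moved
  copies for superposition tests.

Default study conditions: a wild-type inactive:active ratio of 9 (basal
active fraction 10% of span, a receptor with clear but non-saturating
constitutive activity), ago-PAM state selectivity beta = 10 (a moderately
active-state-selective modulator, so that intrinsic agonism co-varies
strongly with constitutive activity across the panel), modulator affinity
for the inactive state 10 µM, 5 replicates, 5% multiplicative noise, and
mutants spanning a 0.6-25-fold change of the inactive:active ratio
relative to wild type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from agopam.dose_response import KineticTrace, four_pl
from agopam.exceptions import UsageError
from agopam.model_core import ConcentrationSeries, TwoStateParameters, response_curve
from agopam.mutant_panel import ConstructRecord
from agopam.structure_volume import AtomSet, RigidTransform

__all__ = [
    "PanelConfig",
    "generate_panel",
    "generate_potentiation_curves",
    "generate_kinetic_trace",
    "generate_geometry_fixtures",
]

#: Default mutant panel: multipliers on the wild-type alpha.  Values > 1
#: suppress constitutive activity (the common mutant phenotype); one mild
#: enhancer mirrors activity-increasing substitutions.
DEFAULT_ALPHA_MULTIPLIERS = {
    "WT": 1.0,
    "M-A": 0.6,
    "M-B": 1.8,
    "M-C": 3.0,
    "M-D": 6.0,
    "M-E": 12.0,
    "M-F": 25.0,
}


@dataclass(frozen=True)
class PanelConfig:
    """Conditions of a simulated mutant-panel experiment."""

    alpha_wt: float = 9.0  # WT basal active fraction = 1/(1+9) = 10% of span
    alpha_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA_MULTIPLIERS))
    pam_params: dict = field(
        default_factory=lambda: {"PAM-1": {"k_inact": 1e-5, "beta": 10.0}}
    )
    concentrations: ConcentrationSeries = field(
        default_factory=lambda: ConcentrationSeries.log_spaced(1e-9, 1e-3, 9)
    )
    signal_floor: float = 20.0  # assay units
    signal_span: float = 1000.0
    n_replicates: int = 5
    noise_cv: float = 0.05
    surface_expression_sd: float = 8.0  # percent spread around 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise UsageError("n_replicates must be >= 2")
        if self.noise_cv < 0:
            raise UsageError("noise_cv must be >= 0")
        if not self.alpha_multipliers or "WT" not in self.alpha_multipliers:
            raise UsageError("alpha_multipliers must include 'WT'")
        if any(m <= 0 for m in self.alpha_multipliers.values()):
            raise UsageError("alpha multipliers must be > 0")

    def construct_params(self, construct_id: str, pam_id: str) -> TwoStateParameters:
        """Generating two-state parameters for one construct/PAM pair."""
        pam = self.pam_params[pam_id]
        return TwoStateParameters(
            alpha=self.alpha_wt * self.alpha_multipliers[construct_id],
            k_inact=pam["k_inact"],
            beta=pam["beta"],
            signal_floor=self.signal_floor,
            signal_span=self.signal_span,
        )


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_panel(config: PanelConfig):
    """Simulate a full mutant panel with known ground truth.

    Returns ``(table, records, manifest)``:

    * ``table`` — tidy replicate-level dose-response rows (one per
      construct x PAM x concentration x replicate), responses on the model
      curve perturbed by multiplicative log-normal noise;
    * ``records`` — one :class:`ConstructRecord` per construct with noisy
      basal replicates and PAM intrinsic-agonism replicates (saturating
      response minus the construct's own mean basal);
    * ``manifest`` — every generating parameter, for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    concs = config.concentrations.as_array()
    rows, records = [], []
    manifest = {
        "seed": config.seed,
        "alpha_wt": config.alpha_wt,
        "noise_cv": config.noise_cv,
        "n_replicates": config.n_replicates,
        "constructs": {},
    }
    for construct_id, mult in config.alpha_multipliers.items():
        alpha = config.alpha_wt * mult
        basal_true = config.signal_floor + config.signal_span / (1.0 + alpha)
        basal_reps = basal_true * _lognormal_factors(rng, config.noise_cv, config.n_replicates)
        pam_reps = {}
        for pam_id in config.pam_params:
            params = config.construct_params(construct_id, pam_id)
            curve = response_curve(params, config.concentrations)
            for rep in range(1, config.n_replicates + 1):
                noisy = curve * _lognormal_factors(rng, config.noise_cv, curve.size)
                for conc, resp in zip(concs, noisy):
                    rows.append(
                        {
                            "construct_id": construct_id,
                            "ligand_id": pam_id,
                            "log10_conc": np.log10(conc),
                            "replicate": rep,
                            "response": resp,
                        }
                    )
            # intrinsic agonism endpoint: saturating PAM response minus basal
            sat_true = params.signal_floor + params.signal_span * (
                params.beta / (params.alpha + params.beta)
            )
            sat_reps = sat_true * _lognormal_factors(rng, config.noise_cv, config.n_replicates)
            pam_reps[pam_id] = tuple(np.maximum(sat_reps - basal_reps.mean(), 0.0))
        expression = float(
            np.clip(rng.normal(100.0, config.surface_expression_sd), 5.0, None)
        )
        records.append(
            ConstructRecord(
                construct_id=construct_id,
                surface_expression=expression if construct_id != "WT" else 100.0,
                basal_signal=tuple(basal_reps),
                pam_agonist_response=pam_reps,
            )
        )
        manifest["constructs"][construct_id] = {
            "alpha": alpha,
            "basal_true": basal_true,
            "pam": {
                pam_id: dict(config.pam_params[pam_id]) for pam_id in config.pam_params
            },
        }
    table = pd.DataFrame(rows)
    return table, records, manifest


def generate_potentiation_curves(
    pam_concs,
    baseline=(0.0, 100.0, -6.0, 1.0),
    pam_ec50: float = 1e-6,
    max_log_shift: float = 0.5,
    emax_factor: float = 1.0,
    agonist_log_concs=None,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Orthosteric-agonist curve family at rising modulator concentrations.

    At modulator concentration ``m`` with fractional occupancy
    ``occ = m / (m + pam_ec50)``, the agonist curve's midpoint shifts left
    by ``max_log_shift * occ`` log units and its Top scales by
    ``1 + (emax_factor - 1) * occ``.  The ``condition`` column records the
    modulator concentration; zero modulator reproduces the baseline curve.
    """
    rng = np.random.default_rng(seed)
    bottom, top, log_ec50, hill = baseline
    if agonist_log_concs is None:
        agonist_log_concs = np.linspace(-9.0, -3.0, 9)
    agonist_log_concs = np.asarray(agonist_log_concs, dtype=float)
    rows = []
    for m in np.asarray(pam_concs, dtype=float):
        occ = m / (m + pam_ec50) if m > 0 else 0.0
        le = log_ec50 - max_log_shift * occ
        tp = top * (1.0 + (emax_factor - 1.0) * occ)
        curve = four_pl(agonist_log_concs, bottom, tp, le, hill)
        for rep in range(1, n_replicates + 1):
            noisy = curve * _lognormal_factors(rng, noise_cv, curve.size)
            for x, y in zip(agonist_log_concs, noisy):
                rows.append(
                    {
                        "construct_id": "WT",
                        "ligand_id": "agonist",
                        "log10_conc": x,
                        "replicate": rep,
                        "response": y,
                        "condition": f"PAM={m:.3g}",
                    }
                )
    return pd.DataFrame(rows)


def generate_kinetic_trace(
    amplitude: float,
    tau: float,
    stimulus_time: float = 60.0,
    duration: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
) -> KineticTrace:
    """Baseline-then-exponential trace: ``amplitude * (1 - exp(-t'/tau))``
    after the stimulus, plus additive Gaussian noise."""
    if tau <= 0:
        raise UsageError("tau must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    signal = np.where(
        t < stimulus_time, 0.0, amplitude * (1.0 - np.exp(-(t - stimulus_time) / tau))
    )
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, t.size)
    return KineticTrace(time=tuple(t), signal=tuple(signal), stimulus_time=stimulus_time)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Near-uniform points on a sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return radius * np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])


def _write_pdb(atoms: AtomSet, path) -> None:
    records = []
    for i in range(len(atoms)):
        x, y, z = atoms.coords[i]
        rec = "HETATM" if atoms.is_ligand[i] else "ATOM  "
        resname = atoms.resnames[i] or ("LIG" if atoms.is_ligand[i] else "GLY")
        chain = atoms.chains[i] or ("L" if atoms.is_ligand[i] else "A")
        name = atoms.atom_names[i] or atoms.elements[i]
        records.append(
            f"{rec}{i + 1:5d} {name:>4s} {resname:>3s} {chain:1s}"
            f"{atoms.resnums[i] or i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00          {atoms.elements[i]:>2s}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(records)
        fh.write("END\n")


def generate_geometry_fixtures(seed: int = 0, outdir=None, inner_radius: float = 4.0):
    """Synthetic geometry with analytically known answers.

    Returns a dict with:

    * ``shell`` — a hollow spherical pseudo-protein: two dense concentric
      layers of carbon-like atoms whose inner vdW surface sits at
      ``inner_radius``, so the enclosed cavity volume is exactly
      ``4/3 * pi * inner_radius**3``;
    * ``cavity_volume`` — that analytic volume (Å³);
    * ``ligand`` — a small rigid 5-atom pseudo-ligand centered in the cavity;
    * ``ligand_moved`` / ``transform`` — a rigidly rotated + translated copy
      of the ligand and the exact motion applied, for superposition tests.

    With ``outdir`` set, the shell and both ligand copies are also written
    as PDB files (``shell.pdb``, ``ligand.pdb``, ``ligand_moved.pdb``).
    All outputs are deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    r_atom = 1.7
    layers = []
    for layer_r, n in ((inner_radius + r_atom, 600), (inner_radius + r_atom + 1.2, 800)):
        layers.append(_fibonacci_sphere(n, layer_r))
    shell_coords = np.vstack(layers)
    shell = AtomSet.from_arrays(
        ["C"] * len(shell_coords),
        shell_coords,
        is_ligand=np.zeros(len(shell_coords), dtype=bool),
        chains=("A",) * len(shell_coords),
        resnames=("GLY",) * len(shell_coords),
        resnums=tuple(range(1, len(shell_coords) + 1)),
        atom_names=("CA",) * len(shell_coords),
    )
    # rigid tetrahedral pseudo-ligand, ~1.5 Å bonds, centered at the origin
    lig_coords = 1.5 / np.sqrt(3.0) * np.array(
        [[0.0, 0.0, 0.0], [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
    )
    ligand = AtomSet.from_arrays(
        ["C"] * 5,
        lig_coords,
        is_ligand=np.ones(5, dtype=bool),
        chains=("L",) * 5,
        resnames=("LIG",) * 5,
        resnums=(1,) * 5,
        atom_names=("C1", "C2", "C3", "C4", "C5"),
    )
    # random proper rotation via QR, plus a translation
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-10.0, 10.0, size=3)
    transform = RigidTransform(rotation=Q, translation=t)
    ligand_moved = ligand.transformed(transform)
    out = {
        "shell": shell,
        "cavity_volume": 4.0 / 3.0 * np.pi * inner_radius**3,
        "inner_radius": inner_radius,
        "ligand": ligand,
        "ligand_moved": ligand_moved,
        "transform": transform,
    }
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_pdb(shell, outdir / "shell.pdb")
        _write_pdb(ligand, outdir / "ligand.pdb")
        _write_pdb(ligand_moved, outdir / "ligand_moved.pdb")
        out["files"] = {
            "shell": str(outdir / "shell.pdb"),
            "ligand": str(outdir / "ligand.pdb"),
            "ligand_moved": str(outdir / "ligand_moved.pdb"),
        }
    return out
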
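"""Scene configuration, end-to-end runs, fixtures and the command-line tool.

A scene config (YAML or JSON) fully determines a computation:

.. code-block:: yaml

    solvent: {eps_sol: 80.0, debye_length: 8.071, temperature: 298.15}
    particles:
      - shape: {type: cone, z0: 10.0}
        eps_in: 2.0
        charges: [[0.0, 0.0, 0.0, 10.0]]   # inline x y z q rows
      - shape: {type: cone, z0: 10.0, mirror: true}
        eps_in: 2.0
        charges: [[0.0, 0.0, 0.0, 10.0]]
    separation: 50.0
    n_max: 6
    solver: {mode: direct}

Shapes: sphere (radius), cone (z0), cylinder (z0, h), perturbed_sphere
(a0, perturbations, seed).  Charges may be inline rows or a
``charges_file`` (PQR or XYZQ).  The solvent accepts ``debye_length`` (A)
or ``ionic_strength`` (mol/L).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from typing import Dict, List, Optional

import click
import numpy as np
import yaml

from .assembly import AssemblyOptions, Scene
from .constants import SolventModel
from .observables import (
    EnergyReport,
    FieldSolution,
    energy_profile,
    potential_on_grid,
    solve_scene,
    total_energy,
    write_dx,
)
from .shapes import make_cone, make_cylinder, make_perturbed_sphere, make_sphere, mirror
from .sources import ChargeSet, ParticleModel, read_charges, write_xyzq

logger = logging.getLogger("debyepair")

__all__ = ["SceneConfig", "load_config", "run", "make_fixture", "cli", "RunResult"]


@dataclasses.dataclass
class SceneConfig:
    """Validated scene description (see the module docstring for the schema)."""

    scene: Scene
    n_max: int
    solver: Dict[str, object]
    options: AssemblyOptions
    seed: Optional[int] = None
    raw: Optional[dict] = None


def _build_shape(spec: dict, base_dir: pathlib.Path):
    kind = spec.get("type")
    if kind == "sphere":
        shape = make_sphere(float(spec["radius"]))
    elif kind == "cone":
        shape = make_cone(float(spec["z0"]))
    elif kind == "cylinder":
        shape = make_cylinder(float(spec["z0"]), float(spec["h"]))
    elif kind == "perturbed_sphere":
        perts = [tuple(p) for p in spec.get("perturbations", [])]
        shape = make_perturbed_sphere(float(spec["a0"]), perts, spec.get("seed"))
    else:
        raise ValueError(f"particles[].shape.type: unknown shape {kind!r}")
    if spec.get("mirror"):
        shape = mirror(shape)
    return shape


def _build_charges(spec: dict, base_dir: pathlib.Path) -> ChargeSet:
    if "charges_file" in spec:
        path = pathlib.Path(spec["charges_file"])
        if not path.is_absolute():
            path = base_dir / path
        return read_charges(path)
    rows = spec.get("charges", [])
    if not rows:
        return ChargeSet(np.zeros((0, 3)), np.zeros(0))
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("particles[].charges: need rows of [x, y, z, q]")
    return ChargeSet(arr[:, :3], arr[:, 3])


def parse_config(data: dict, base_dir: pathlib.Path = pathlib.Path(".")) -> SceneConfig:
    try:
        sv = data["solvent"]
        if "debye_length" in sv:
            solvent = SolventModel(
                eps_sol=float(sv["eps_sol"]),
                debye_length=float(sv["debye_length"]),
                temperature=float(sv.get("temperature", 298.15)),
            )
        else:
            solvent = SolventModel.from_ionic_strength(
                eps_sol=float(sv["eps_sol"]),
                ionic_strength_molar=float(sv["ionic_strength"]),
                temperature=float(sv.get("temperature", 298.15)),
            )
    except KeyError as exc:
        raise ValueError(f"solvent: missing field {exc}") from exc
    particles = []
    for k, p in enumerate(data.get("particles", [])):
        try:
            particles.append(
                ParticleModel(
                    shape=_build_shape(p["shape"], base_dir),
                    eps_in=float(p["eps_in"]),
                    charges=_build_charges(p, base_dir),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"particles[{k}]: {exc}") from exc
    R = data.get("separation")
    scene = Scene(tuple(particles), solvent, None if R is None else float(R))
    opts = AssemblyOptions(force_full=bool(data.get("force_full", False)))
    solver = dict(data.get("solver", {"mode": "direct"}))
    solver.setdefault("mode", "direct")
    return SceneConfig(
        scene=scene,
        n_max=int(data["n_max"]),
        solver=solver,
        options=opts,
        seed=data.get("seed"),
        raw=data,
    )


def load_config(path) -> SceneConfig:
    path = pathlib.Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    return parse_config(data, base_dir=path.parent)


@dataclasses.dataclass
class RunResult:
    solution: FieldSolution
    energy: EnergyReport
    timings: Dict[str, float]

    def summary(self) -> dict:
        rep = self.solution.report
        return {
            "n_max": self.solution.n_max,
            "W_kBT": self.energy.W,
            "W_Born_kBT": self.energy.W_Born,
            "W_int_kBT": self.energy.W_int,
            "condition_number": rep.condition_number,
            "residual_norm": rep.residual_norm,
            "solver_mode": rep.mode,
            "alpha": rep.alpha,
            "timings_s": self.timings,
        }


def run(config: SceneConfig) -> RunResult:
    """Assemble, solve and evaluate energies for a configured scene."""
    solver = dict(config.solver)
    mode = solver.pop("mode")
    t0 = time.perf_counter()
    sol = solve_scene(config.scene, config.n_max, mode, config.options, **solver)
    t1 = time.perf_counter()
    logger.info("solve stage done", extra={"stage": "solve", "seconds": t1 - t0})
    energy = total_energy(sol, mode=mode, **solver)
    t2 = time.perf_counter()
    logger.info("energy stage done", extra={"stage": "energy", "seconds": t2 - t1})
    return RunResult(
        solution=sol,
        energy=energy,
        timings={"assemble_solve": t1 - t0, "energy": t2 - t1},
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _synthetic_amino_charges(kind: str, rng: np.random.Generator) -> ChargeSet:
    """Synthetic stand-ins for the arginine/glutamate charge sets (the real
    force-field coordinates are not shipped): a few point charges on an
    amino-acid length scale with the correct net charge (+1 e for arginine,
    -1 e for glutamate)."""
    if kind == "arg":
        base = np.array(
            [[0.0, 0.0, -1.2], [0.6, 0.4, -0.2], [-0.5, 0.3, 0.6], [0.1, -0.5, 1.1]]
        )
        q = np.array([0.30, 0.35, 0.25, 0.10])
    else:
        base = np.array([[0.0, 0.0, 1.0], [0.5, -0.3, 0.0], [-0.4, 0.2, -0.8]])
        q = np.array([-0.45, -0.35, -0.20])
    jitter = rng.normal(scale=0.02, size=base.shape)
    return ChargeSet(base + jitter, q)


FIXTURE_NAMES = ("cones", "cylinders", "arg_glu", "two_spheres", "perturbed")


def make_fixture(name: str, out_dir, seed: int = 0) -> List[pathlib.Path]:
    """Write the configuration (and charge files) of a named model scene.

    cones / cylinders: the benchmark pairs (z0 = 10 A, central 10 e charges,
    eps_in = 2, Debye length 8.071 A, eps_sol = 80) at R = 25 and 50 A.
    arg_glu: synthetic amino-acid charge sets in two small cylinders with
    the separation sweep 8.54..14.94 A (step 0.1).  two_spheres: the
    closed-form comparison pair.  perturbed: seed-reproducible
    non-symmetric shapes.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    solvent = {"eps_sol": 80.0, "debye_length": 8.071, "temperature": 298.15}
    written = []

    def dump(fname: str, data: dict) -> None:
        p = out / fname
        with open(p, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        written.append(p)

    if name == "cones":
        for R in (25.0, 50.0):
            dump(
                f"cones_R{int(R)}.yaml",
                {
                    "solvent": solvent,
                    "particles": [
                        {"shape": {"type": "cone", "z0": 10.0}, "eps_in": 2.0,
                         "charges": [[0.0, 0.0, 0.0, 10.0]]},
                        {"shape": {"type": "cone", "z0": 10.0, "mirror": True},
                         "eps_in": 2.0, "charges": [[0.0, 0.0, 0.0, 10.0]]},
                    ],
                    "separation": R,
                    "n_max": 6,
                    "solver": {"mode": "direct"},
                },
            )
    elif name == "cylinders":
        for R in (25.0, 50.0):
            dump(
                f"cylinders_R{int(R)}.yaml",
                {
                    "solvent": solvent,
                    "particles": [
                        {"shape": {"type": "cylinder", "z0": 10.0, "h": 50.0},
                         "eps_in": 2.0, "charges": [[0.0, 0.0, 0.0, 10.0]]},
                        {"shape": {"type": "cylinder", "z0": 10.0, "h": 50.0},
                         "eps_in": 2.0, "charges": [[0.0, 0.0, 0.0, 10.0]]},
                    ],
                    "separation": R,
                    "n_max": 10,
                    "solver": {"mode": "direct"},
                },
            )
    elif name == "arg_glu":
        glu = _synthetic_amino_charges("glu", rng)
        arg = _synthetic_amino_charges("arg", rng)
        write_xyzq(out / "glu_synthetic.xyzq", glu)
        write_xyzq(out / "arg_synthetic.xyzq", arg)
        written += [out / "glu_synthetic.xyzq", out / "arg_synthetic.xyzq"]
        R_values = [round(8.54 + 0.1 * k, 2) for k in range(65)]
        dump(
            "arg_glu.yaml",
            {
                "solvent": solvent,
                "particles": [
                    {"shape": {"type": "cylinder", "z0": 2.0, "h": 3.5},
                     "eps_in": 2.0, "charges_file": "glu_synthetic.xyzq"},
                    {"shape": {"type": "cylinder", "z0": 2.0, "h": 3.5},
                     "eps_in": 2.0, "charges_file": "arg_synthetic.xyzq"},
                ],
                "separation": R_values[0],
                "separation_sweep": R_values,
                "n_max": 8,
                "solver": {"mode": "direct"},
            },
        )
    elif name == "two_spheres":
        dump(
            "two_spheres.yaml",
            {
                "solvent": solvent,
                "particles": [
                    {"shape": {"type": "sphere", "radius": 10.0}, "eps_in": 2.0,
                     "charges": [[0.0, 0.0, 0.0, 10.0]]},
                    {"shape": {"type": "sphere", "radius": 10.0}, "eps_in": 2.0,
                     "charges": [[0.0, 0.0, 0.0, 10.0]]},
                ],
                "separation": 50.0,
                "n_max": 6,
                "solver": {"mode": "direct"},
            },
        )
    elif name == "perturbed":
        perts = [[2, 0, "cos", float(rng.uniform(-0.05, 0.05))],
                 [3, 2, "cos", float(rng.uniform(-0.05, 0.05))],
                 [2, 1, "sin", float(rng.uniform(-0.05, 0.05))]]
        dump(
            "perturbed.yaml",
            {
                "solvent": solvent,
                "particles": [
                    {"shape": {"type": "perturbed_sphere", "a0": 10.0,
                               "perturbations": perts, "seed": seed},
                     "eps_in": 2.0, "charges": [[0.0, 0.0, 1.0, 5.0]]},
                    {"shape": {"type": "sphere", "radius": 8.0}, "eps_in": 2.0,
                     "charges": [[0.0, 0.0, 0.0, 5.0]]},
                ],
                "separation": 40.0,
                "n_max": 4,
                "solver": {"mode": "direct"},
                "seed": seed,
            },
        )
    return written


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="log per-stage details")
def cli(verbose: bool) -> None:
    """Semi-analytical Debye-Huckel solver for two dielectric particles."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING)


@cli.command("solve")
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None, help="write a JSON summary")
def cli_solve(config_path, out):
    """Solve a scene config and report the energies."""
    config = load_config(config_path)
    result = run(config)
    summary = result.summary()
    click.echo(json.dumps(summary, indent=2, default=float))
    if out:
        pathlib.Path(out).write_text(json.dumps(summary, indent=2, default=float))


@cli.command("profile")
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--r-min", type=float, required=True)
@click.option("--r-max", type=float, required=True)
@click.option("--r-step", type=float, required=True)
@click.option("--out", type=click.Path(), default="profile.csv")
def cli_profile(config_path, r_min, r_max, r_step, out):
    """Energy-vs-separation profile written as CSV."""
    config = load_config(config_path)
    solver = dict(config.solver)
    mode = solver.pop("mode")
    R_values = np.arange(r_min, r_max + 0.5 * r_step, r_step)
    df = energy_profile(config.scene.particles, config.scene.solvent, R_values,
                        config.n_max, mode, config.options, **solver)
    df.to_csv(out, index=False)
    click.echo(f"wrote {out} ({len(df)} rows)")


@cli.command("map")
@click.argument("config_path", type=click.Path(exists=True))
@click.option("--plane", default="x=0", help="slice plane, e.g. x=0")
@click.option("--spacing", type=float, default=0.25)
@click.option("--clearance", type=float, default=2.0)
@click.option("--pad", type=float, default=30.0, help="margin around the particles (A)")
@click.option("--out", type=click.Path(), default="potential.dx")
def cli_map(config_path, plane, spacing, clearance, pad, out):
    """Potential map on a plane, written as OpenDX (and CSV alongside)."""
    config = load_config(config_path)
    solver = dict(config.solver)
    mode = solver.pop("mode")
    sol = solve_scene(config.scene, config.n_max, mode, config.options, **solver)
    axis, value = plane.split("=")
    value = float(value)
    ext = max(p.shape.a_max for p in config.scene.particles) + pad
    lo, hi = -ext, ext + (config.scene.R or 0.0)
    side = np.arange(-ext, ext + spacing, spacing)
    zax = np.arange(lo, hi + spacing, spacing)
    grids = {"x": side, "y": side, "z": zax}
    grids[axis.strip()] = np.array([value])
    vals = potential_on_grid(sol, grids["x"], grids["y"], grids["z"], clearance)
    write_dx(out, vals, (grids["x"][0], grids["y"][0], grids["z"][0]),
             (spacing, spacing, spacing))
    np.savetxt(str(out) + ".csv", vals.reshape(vals.shape[0], -1), delimiter=",")
    click.echo(f"wrote {out}")


@cli.command("fixture")
@click.argument("name", type=click.Choice(FIXTURE_NAMES))
@click.option("--out-dir", type=click.Path(), default="fixtures")
@click.option("--seed", type=int, default=0)
def cli_fixture(name, out_dir, seed):
    """Write a named model-scene fixture (config + charge files)."""
    for p in make_fixture(name, out_dir, seed):
        click.echo(str(p))
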
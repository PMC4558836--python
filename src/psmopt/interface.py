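"""File formats, configuration, pipeline wiring and the command line.

MGF is the spectrum exchange format (read/written through pyteomics); PSM
lists travel as TSV tables.  All randomness in a run flows from one seed
through named sub-streams (simulate / ga / folds), so end-to-end runs are
bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import click
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from . import __version__
from .confidence import FitnessConfig, assign_qvalues, fitness
from .optimizer import GAConfig, GeneKind, ParamSpec, run_ga
from .peptide_space import (
    Fidelity,
    NTermMod,
    ProteinRecord,
    digest_proteome,
)
from .rt_suite import RTSelectionConfig
from .search_core import SearchParams, Spectrum, search_dataset
from .synthetic_data import SimConfig, generate_proteome, simulate_dataset

logger = logging.getLogger(__name__)

PSM_TABLE_COLUMNS = [
    "spectrum_id",
    "peptide",
    "nterm_mod",
    "charge",
    "score",
    "raw_delta_da",
    "isotope_offset",
    "is_decoy",
    "q_value",
    "rt_observed",
]


class MGFFormatError(ValueError):
    """Malformed MGF input."""


def read_mgf(path, default_charge: int = 2) -> list:
    """Read spectra from an MGF file.

    RTINSECONDS is converted to minutes; a missing CHARGE falls back to
    ``default_charge`` with a warning.
    """
    spectra = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                title = str(params.get("title", f"index={i}"))
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    raise MGFFormatError(
                        f"{path}: spectrum {title!r} (block {i + 1}) lacks PEPMASS"
                    )
                charge_field = params.get("charge")
                if charge_field:
                    charge = int(charge_field[0])
                else:
                    logger.warning(
                        "%s: spectrum %r has no CHARGE; assuming %d+",
                        path, title, default_charge,
                    )
                    charge = default_charge
                rt_s = params.get("rtinseconds", 0.0)
                spectra.append(
                    Spectrum(
                        id=title,
                        precursor_mz=float(pepmass[0]),
                        charge=charge,
                        rt=float(rt_s) / 60.0,
                        peaks=list(
                            zip(entry["m/z array"].tolist(),
                                entry["intensity array"].tolist())
                        ),
                    )
                )
    except MGFFormatError:
        raise
    except Exception as exc:
        raise MGFFormatError(f"{path}: malformed MGF ({exc})") from exc
    return spectra


def write_mgf(spectra: Sequence, path) -> None:
    """Write spectra to MGF (TITLE, PEPMASS, CHARGE, RTINSECONDS)."""
    entries = []
    for s in spectra:
        mz = np.array([p[0] for p in s.peaks])
        inten = np.array([p[1] for p in s.peaks])
        entries.append(
            {
                "m/z array": mz,
                "intensity array": inten,
                "params": {
                    "title": s.id,
                    "pepmass": s.precursor_mz,
                    "charge": s.charge,
                    "rtinseconds": s.rt * 60.0,
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh)


def read_fasta(path) -> list:
    """Plain-header FASTA; DECOY_-prefixed ids are flagged as decoys."""
    proteins = []
    pid = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if pid is not None:
                    proteins.append(_protein(pid, chunks))
                pid = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if pid is not None:
            proteins.append(_protein(pid, chunks))
    return proteins


def _protein(pid, chunks):
    return ProteinRecord(
        id=pid, sequence="".join(chunks), is_decoy=pid.startswith("DECOY_")
    )


def write_fasta(proteins: Sequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def write_psm_table(psms: Sequence, path) -> None:
    """PSMs as TSV, floats at 6 decimals; decoy rows included."""
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide.sequence,
            "nterm_mod": p.peptide.nterm_mod.value,
            "charge": p.charge,
            "score": p.score,
            "raw_delta_da": p.raw_delta,
            "isotope_offset": p.isotope_offset,
            "is_decoy": p.is_decoy,
            "q_value": p.q_value,
            "rt_observed": p.rt,
        }
        for p in psms
    ]
    df = pd.DataFrame(rows, columns=PSM_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM TSV back; raises on a header mismatch."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PSM_TABLE_COLUMNS:
        raise ValueError(
            f"{path}: unexpected PSM table header {list(df.columns)}"
        )
    return df


@dataclass
class RunConfig:
    """Serializable configuration of a full run."""

    search: SearchParams = field(default_factory=SearchParams)
    ga: GAConfig = field(default_factory=GAConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    rt: RTSelectionConfig = field(default_factory=RTSelectionConfig)
    log_level: str = "INFO"

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (Fidelity, NTermMod)):
                return obj.value
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return json.dumps(enc(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        sim_raw = dict(raw["sim"])
        sim_raw["charge_probs"] = tuple(sim_raw["charge_probs"])
        return cls(
            search=SearchParams(**raw["search"]),
            ga=GAConfig(**raw["ga"]),
            sim=SimConfig(**sim_raw),
            rt=RTSelectionConfig(**raw["rt"]),
            log_level=raw.get("log_level", "INFO"),
        )


def evaluate_params(spectra, index, params: SearchParams) -> float:
    """Search, assign q-values, and return the fitness of one parameter set."""
    psms = search_dataset(spectra, index, params)
    assign_qvalues(psms)
    cfg = FitnessConfig(
        total_spectra=len(spectra),
        fdr_threshold=params.fdr_threshold,
        charge=params.fitness_charge,
    )
    return fitness(psms, cfg)


def window_objective(
    spectra, index, base: SearchParams
) -> Callable:
    """Objective over (mme_minus, mme_plus) with everything else fixed."""

    def objective(chrom) -> float:
        mme_minus, mme_plus = chrom.values[:2]
        params = dataclasses.replace(
            base, mme_minus=float(mme_minus), mme_plus=float(mme_plus)
        )
        return evaluate_params(spectra, index, params)

    return objective


def window_param_spec(low: float = 0.0, high: float = 25.0) -> list:
    return [
        ParamSpec("mme_minus", GeneKind.CONTINUOUS, low=low, high=high),
        ParamSpec("mme_plus", GeneKind.CONTINUOUS, low=low, high=high),
    ]


def surface_grid(
    mme_minus_values: Sequence,
    mme_plus_values: Sequence,
    objective: Callable,
) -> pd.DataFrame:
    """Fitness over a (mme_minus, mme_plus) grid, sorted rows.

    ``objective`` maps (mme_minus, mme_plus) to a fitness value; the output
    TSV-ready table is suitable for contour plotting.
    """
    rows = [
        {
            "mme_minus": float(mm),
            "mme_plus": float(mp),
            "fitness": float(objective(mm, mp)),
        }
        for mm in sorted(mme_minus_values)
        for mp in sorted(mme_plus_values)
    ]
    return pd.DataFrame(rows, columns=["mme_minus", "mme_plus", "fitness"])


def grid_range(low: float, high: float, step: float) -> list:
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((high - low) / step + 1e-9)) + 1
    return [low + i * step for i in range(n)]


def seed_streams(seed: int) -> dict:
    """Named, independent RNG streams derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "simulate": np.random.default_rng(children[0]),
        "ga": np.random.default_rng(children[1]),
        "folds": np.random.default_rng(children[2]),
    }


def _provenance(outdir: Path, command: str, config: dict, seed: int) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "config": config,
        "seed": seed,
        "versions": {
            "psmopt": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / f"{command}_provenance.json").write_text(
        json.dumps(record, indent=2, sort_keys=True, default=str)
    )


# ---------------------------------------------------------------------------
# command line


@click.group()
@click.version_option(__version__)
def main():
    """Optimize peptide-spectrum-matching workflow parameters."""


def _load_inputs(fasta, mgf, missed, fidelity, default_charge=2):
    proteins = read_fasta(fasta)
    targets = [p for p in proteins if not p.is_decoy]
    index = digest_proteome(targets, missed_max=missed,
                            fidelity=Fidelity(fidelity))
    spectra = read_mgf(mgf, default_charge=default_charge)
    return index, spectra


@main.command()
@click.option("--out", type=click.Path(), required=True,
              help="Output directory.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-spectra", type=int, default=1000, show_default=True)
@click.option("--n-proteins", type=int, default=50, show_default=True)
def simulate(out, seed, n_spectra, n_proteins):
    """Generate a ground-truthed proteome (FASTA), spectra (MGF) and truth TSV."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed, n_spectra=n_spectra, n_proteins=n_proteins)
    rng = seed_streams(seed)["simulate"]
    proteome = generate_proteome(cfg, rng)
    spectra, truth, planted = simulate_dataset(proteome, cfg, rng)
    write_fasta(proteome, outdir / "proteome.fasta")
    write_mgf(spectra, outdir / "spectra.mgf")
    pd.DataFrame(
        [
            {
                "spectrum_id": t.spectrum_id,
                "true_peptide": t.true_peptide or "",
                "event": t.event.value,
                "true_rt": round(t.true_rt, 6),
            }
            for t in truth
        ]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    np.savetxt(outdir / "planted_rt_coefficients.tsv", planted.params,
               fmt="%.8f")
    _provenance(outdir, "simulate", dataclasses.asdict(cfg), seed)
    click.echo(f"wrote {len(spectra)} spectra to {outdir}")


@main.command(name="digest")
@click.option("--fasta", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--missed", type=click.IntRange(0, 4), default=2,
              show_default=True)
@click.option("--fidelity", type=click.Choice(["full", "semi"]),
              default="full", show_default=True)
def digest_cmd(fasta, out, missed, fidelity):
    """Digest a FASTA (targets + reversed decoys) into a peptide table."""
    proteins = read_fasta(fasta)
    targets = [p for p in proteins if not p.is_decoy]
    index = digest_proteome(targets, missed_max=missed,
                            fidelity=Fidelity(fidelity))
    pd.DataFrame(
        [
            {
                "peptide": e.sequence,
                "nterm_mod": e.nterm_mod.value,
                "mass": round(e.mass, 6),
                "n_missed": e.n_missed,
                "is_decoy": e.is_decoy,
                "proteins": ";".join(sorted(e.protein_ids)),
            }
            for e in index.entries
        ]
    ).to_csv(out, sep="\t", index=False)
    click.echo(f"wrote {len(index)} peptide entries to {out}")


@main.command()
@click.option("--fasta", type=click.Path(exists=True), required=True)
@click.option("--mgf", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--mme-minus", type=click.FloatRange(0, 25), default=2.0,
              show_default=True)
@click.option("--mme-plus", type=click.FloatRange(0, 25), default=2.0,
              show_default=True)
@click.option("--isotope-max", type=click.IntRange(0, 2), default=2,
              show_default=True)
@click.option("--missed", type=click.IntRange(0, 4), default=2,
              show_default=True)
@click.option("--fidelity", type=click.Choice(["full", "semi"]),
              default="full", show_default=True)
@click.option("--fdr", type=float, default=0.01, show_default=True)
def search(fasta, mgf, out, mme_minus, mme_plus, isotope_max, missed,
           fidelity, fdr):
    """Search an MGF against a FASTA and write a q-valued PSM table."""
    try:
        index, spectra = _load_inputs(fasta, mgf, missed, fidelity)
    except (OSError, ValueError) as exc:
        raise click.ClickException(str(exc))
    params = SearchParams(
        mme_minus=mme_minus, mme_plus=mme_plus, isotope_max=isotope_max,
        missed_max=missed, fidelity=Fidelity(fidelity), fdr_threshold=fdr,
    )
    psms = search_dataset(spectra, index, params)
    assign_qvalues(psms)
    write_psm_table(psms, out)
    cfg = FitnessConfig(total_spectra=len(spectra), fdr_threshold=fdr)
    click.echo(
        f"{len(psms)} PSMs; fitness={fitness(psms, cfg):.4f} "
        f"({len(spectra)} spectra)"
    )


@main.command()
@click.option("--fasta", type=click.Path(exists=True), required=True)
@click.option("--mgf", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True,
              help="Output directory.")
@click.option("--mme-low", type=float, default=0.0, show_default=True)
@click.option("--mme-high", type=float, default=25.0, show_default=True)
@click.option("--population", type=int, default=20, show_default=True)
@click.option("--generations", type=int, default=30, show_default=True)
@click.option("--missed", type=click.IntRange(0, 4), default=2,
              show_default=True)
@click.option("--fidelity", type=click.Choice(["full", "semi"]),
              default="full", show_default=True)
@click.option("--isotope-max", type=click.IntRange(0, 2), default=2,
              show_default=True)
@click.option("--fdr", type=float, default=0.01, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
def optimize(fasta, mgf, out, mme_low, mme_high, population, generations,
             missed, fidelity, isotope_max, fdr, seed):
    """GA-optimize the precursor tolerance window for fitness at 1% FDR."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        index, spectra = _load_inputs(fasta, mgf, missed, fidelity)
    except (OSError, ValueError) as exc:
        raise click.ClickException(str(exc))
    base = SearchParams(
        isotope_max=isotope_max, missed_max=missed,
        fidelity=Fidelity(fidelity), fdr_threshold=fdr,
    )
    spec = window_param_spec(mme_low, mme_high)
    ga_cfg = GAConfig(population=population, max_generations=generations,
                      stagnation_limit=generations, seed=seed)
    best, log = run_ga(spec, window_objective(spectra, index, base), ga_cfg,
                       rng=seed_streams(seed)["ga"])
    pd.DataFrame(
        [
            {
                "generation": r.generation,
                "best_fitness": r.best_fitness,
                "mean_fitness": r.mean_fitness,
                "best_mme_minus": r.best_values[0],
                "best_mme_plus": r.best_values[1],
                "evaluations": r.evaluations,
            }
            for r in log
        ]
    ).to_csv(outdir / "generations.tsv", sep="\t", index=False,
             float_format="%.6f")
    _provenance(
        outdir, "optimize",
        {"ga": dataclasses.asdict(ga_cfg), "search": dataclasses.asdict(base)},
        seed,
    )
    click.echo(
        f"best fitness {best.fitness:.4f} at MME- {best.values[0]:.2f} Da, "
        f"MME+ {best.values[1]:.2f} Da"
    )


@main.command()
@click.option("--fasta", type=click.Path(exists=True), required=True)
@click.option("--mgf", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--mme-low", type=float, default=0.0, show_default=True)
@click.option("--mme-high", type=float, default=25.0, show_default=True)
@click.option("--step", type=float, default=2.5, show_default=True)
@click.option("--isotope-max", type=click.IntRange(0, 2), default=2,
              show_default=True)
@click.option("--fdr", type=float, default=0.01, show_default=True)
def surface(fasta, mgf, out, mme_low, mme_high, step, isotope_max, fdr):
    """Map the fitness surface over a (MME-, MME+) grid to a TSV."""
    if step <= 0:
        raise click.UsageError("step must be positive")
    try:
        index, spectra = _load_inputs(fasta, mgf, 2, "full")
    except (OSError, ValueError) as exc:
        raise click.ClickException(str(exc))
    base = SearchParams(isotope_max=isotope_max, fdr_threshold=fdr)

    def objective(mm, mp):
        params = dataclasses.replace(base, mme_minus=mm, mme_plus=mp)
        return evaluate_params(spectra, index, params)

    values = grid_range(mme_low, mme_high, step)
    grid = surface_grid(values, values, objective)
    grid.to_csv(out, sep="\t", index=False, float_format="%.6f")
    click.echo(f"wrote {len(grid)} grid points to {out}")


@main.command(name="rt-select")
@click.option("--psms", "psm_path", type=click.Path(exists=True),
              required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--val-cutoff", type=float, default=0.99, show_default=True)
@click.option("--folds", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
def rt_select(psm_path, out, val_cutoff, folds, seed):
    """Cross-validated RMSD model selection on a PSM table."""
    from .rt_suite import AllInfeasibleError, RTObservation, select_rt_model

    df = read_psm_table(psm_path)
    df = df[~df["is_decoy"]]
    obs = [
        RTObservation(sequence=r.peptide, rt=r.rt_observed,
                      confidence=1.0 - r.q_value)
        for r in df.itertuples()
    ]
    cfg = RTSelectionConfig(folds=folds, validation_cutoff=val_cutoff,
                            seed=seed)
    try:
        kind, cutoff, table = select_rt_model(obs, cfg=cfg)
    except AllInfeasibleError as exc:
        raise click.ClickException(str(exc))
    table.to_csv(out, sep="\t", index=False, float_format="%.6f")
    click.echo(f"selected {kind.value} at training cutoff {cutoff}")


@main.command(name="rt-filter")
@click.option("--psms", "psm_path", type=click.Path(exists=True),
              required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--zscore", type=float, default=2.0, show_default=True)
@click.option("--train-cutoff", type=float, default=0.99, show_default=True)
def rt_filter(psm_path, out, zscore, train_cutoff):
    """Fit the composition-linear RT model and drop |Z| > threshold rows."""
    from .rt_suite import Infeasible, RTKind, fit_model, predict

    df = read_psm_table(psm_path)
    confident = df[(~df["is_decoy"]) & (df["q_value"] <= 1.0 - train_cutoff)]
    train = list(zip(confident["peptide"], confident["rt_observed"]))
    model = fit_model(RTKind.LINEAR_COMPOSITION, train)
    if isinstance(model, Infeasible):
        raise click.ClickException(f"RT model infeasible: {model.reason}")
    preds = np.array([predict(model, s) for s in df["peptide"]])
    z = (df["rt_observed"].to_numpy() - preds) / model.residual_sd
    kept = df[np.abs(z) <= zscore]
    kept.to_csv(out, sep="\t", index=False, float_format="%.6f")
    click.echo(f"kept {len(kept)} of {len(df)} PSMs at |Z| <= {zscore}")


if __name__ == "__main__":
    main()
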
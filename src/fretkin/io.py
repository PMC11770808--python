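"""Readers/writers, run configuration and the end-to-end synthetic demo.

Photon data round-trips through an HDF5 layout modeled on Photon-HDF5
(``photon_data/timestamps``, ``photon_data/detectors`` plus excitation
labels and clock metadata under ``setup``) or through columnar text with
``#``-prefixed metadata headers.  All writes are atomic (temp file +
rename); outputs embed the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .photons import PhotonDataset, PhotonStream


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_photon_hdf5(dataset: PhotonDataset, path) -> None:
    import h5py

    def _write(tmp: Path) -> None:
        with h5py.File(tmp, "w") as f:
            g = f.create_group("photon_data")
            g.create_dataset("timestamps", data=dataset.stream.timestamps)
            g.create_dataset("detectors", data=dataset.stream.detection)
            g.create_dataset("excitation", data=dataset.stream.excitation)
            setup = f.create_group("setup")
            setup.attrs["clock_period_s"] = dataset.stream.clock_period
            f.attrs["meta"] = json.dumps(dataset.meta, default=str)

    _atomic_write(Path(path), _write)


def write_photon_text(dataset: PhotonDataset, path) -> None:
    def _write(tmp: Path) -> None:
        with open(tmp, "w") as f:
            f.write(f"# clock_period_s = {dataset.stream.clock_period!r}\n")
            for k, v in dataset.meta.items():
                f.write(f"# {k} = {v}\n")
            f.write("timestamp_ticks\texcitation\tdetection\n")
            np.savetxt(
                f,
                np.column_stack([dataset.stream.timestamps, dataset.stream.excitation,
                                 dataset.stream.detection]),
                fmt="%d", delimiter="\t",
            )

    _atomic_write(Path(path), _write)


def read_photon_data(path) -> PhotonDataset:
    """Load a photon dataset from HDF5 or columnar text; validates the stream."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            if "setup" not in f or "clock_period_s" not in f["setup"].attrs:
                raise ValueError("missing clock metadata (setup/clock_period_s)")
            stream = PhotonStream(
                f["photon_data/timestamps"][:],
                f["photon_data/excitation"][:],
                f["photon_data/detectors"][:],
                float(f["setup"].attrs["clock_period_s"]),
            )
            meta = json.loads(f.attrs.get("meta", "{}"))
    else:
        meta = {}
        clock = None
        with open(path) as f:
            for line in f:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition("=")
                key = key.strip()
                if key == "clock_period_s":
                    clock = float(val)
                else:
                    meta[key] = val.strip()
        if clock is None:
            raise ValueError("missing clock metadata (# clock_period_s header)")
        arr = pd.read_csv(path, sep="\t", comment="#").to_numpy()
        stream = PhotonStream(arr[:, 0], arr[:, 1], arr[:, 2], clock)
    stream.validate()
    return PhotonDataset(stream, meta=meta)


def write_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Columnar text with ``#``-prefixed metadata header."""
    meta = dict(meta or {})
    for k, v in table.attrs.items():
        meta.setdefault(k, v)

    def _write(tmp: Path) -> None:
        with open(tmp, "w") as f:
            for k, v in meta.items():
                f.write(f"# {k} = {v}\n")
            table.to_csv(f, sep="\t", index=False)

    _atomic_write(Path(path), _write)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
    table.attrs.update(meta)
    return table


@dataclass
class RunConfig:
    """Seeded configuration of an end-to-end run."""

    seed: int = 1
    n_bursts: int = 4000
    k_open: float = 4e4
    k_close: float = 4e4
    e_open: float = 0.37
    e_closed: float = 0.72
    velocity_sem: float = 0.5  # 1/s, absolute SEM on simulated velocities
    amp_grid_um: tuple = (50, 100, 200, 400, 800, 1500, 3000, 5000, 10_000)
    urea_levels: tuple = (0.0, 0.4, 0.8)
    outdir: str | None = None
    extra: dict = field(default_factory=dict)

    def hash(self) -> str:
        payload = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        if "seed" not in d:
            raise ValueError("config must record an explicit seed")
        known = {k: d.pop(k) for k in list(d) if k in cls.__dataclass_fields__}
        for k in ("amp_grid_um", "urea_levels"):
            if k in known:
                known[k] = tuple(known[k])
        return cls(**known, extra=d) if d else cls(**known)

    def to_yaml(self, path) -> None:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(yaml.safe_dump(payload)))


def run_demo(config: RunConfig) -> dict:
    """One-command synthetic demonstration of the full pipeline.

    Simulates photons -> burst search -> photon-by-photon HMM -> validation
    -> K_C, and velocities -> global fit, then reports recovery errors in a
    machine-readable dict.  Deterministic under the config seed.
    """
    from . import bursts as bmod
    from . import h2mm, hmm_validate, kinfit, synth
    from .kinscheme import wild_type_scheme

    config_hash = config.hash()
    report: dict = {"seed": config.seed, "config_hash": config_hash}
    stage = "simulate_photons"
    try:
        cfg = synth.SimConfig(
            k_open=config.k_open, k_close=config.k_close,
            E_open=config.e_open, E_closed=config.e_closed,
            n_bursts=config.n_bursts, seed=config.seed,
        )
        ds = synth.simulate_dataset(cfg)

        stage = "burst_search"
        table = bmod.find_bursts(ds.stream)
        burst_photons = bmod.extract_burst_photons(ds, table)
        report["n_bursts_found"] = len(table)

        stage = "h2mm_fit"
        model, record = h2mm.fit_two_state(burst_photons, ds.clock_period)
        order = np.argsort(model.E)
        e_fit = model.E[order]
        report["h2mm"] = {
            "E_open": float(e_fit[0]), "E_closed": float(e_fit[1]),
            "E_open_err": float(abs(e_fit[0] - config.e_open)),
            "E_closed_err": float(abs(e_fit[1] - config.e_closed)),
            "converged": record.converged,
            "loglik": record.loglik,
        }
        open_idx, closed_idx = int(order[0]), int(order[1])
        k_close_hat = model.Q[open_idx, closed_idx]
        k_open_hat = model.Q[closed_idx, open_idx]
        report["h2mm"]["k_close_rel_err"] = float(abs(k_close_hat - config.k_close) / config.k_close)
        report["h2mm"]["k_open_rel_err"] = float(abs(k_open_hat - config.k_open) / config.k_open)
        _, _, kc = h2mm.populations_kc(model)
        report["h2mm"]["K_C"] = kc

        stage = "validation"
        _, dist = hmm_validate.recolor(model, burst_photons, ds.clock_period, seed=config.seed)
        null = hmm_validate.recolor_null(model, burst_photons, ds.clock_period,
                                         n_draws=10, seed=config.seed + 1)
        bva = hmm_validate.burst_variance_analysis(burst_photons, n=5)
        report["validation"] = {
            "recolor_distance": dist,
            "recolor_null_95": float(np.quantile(null, 0.95)),
            "bva_mean_sd": float(bva["sd_E"].mean()),
            "bva_mean_envelope": float(bva["static_envelope"].mean()),
        }

        stage = "velocity_fit"
        truth = {u: wild_type_scheme(u) for u in config.urea_levels}
        frames = [
            synth.simulate_velocity_data(truth[u], config.amp_grid_um,
                                         sem=config.velocity_sem, seed=config.seed + i,
                                         urea=u)
            for i, u in enumerate(config.urea_levels)
        ]
        data = pd.concat(frames, ignore_index=True)
        fit = kinfit.global_fit(data, truth, seed=config.seed)
        report["kinetics"] = {
            "chi2_red": fit.chi2_red,
            **{
                f"{p}_rel_err": float(abs(fit.params[p] - getattr(truth[0.0], p))
                                      / getattr(truth[0.0], p))
                for p in kinfit.FREE_PARAMS
            },
        }
        tolerances = {"E_open_err": 0.02, "E_closed_err": 0.02,
                      "k_close_rel_err": 0.2, "k_open_rel_err": 0.2,
                      "k_cat_rel_err": 0.1, "k_r_T_rel_err": 0.1, "k_r_M_rel_err": 0.25}
        flags = {}
        for key, tol in tolerances.items():
            for section in ("h2mm", "kinetics"):
                if key in report.get(section, {}):
                    flags[key] = bool(report[section][key] > tol)
        report["recovery_flags"] = flags
    except Exception as err:
        raise RuntimeError(f"demo failed at stage '{stage}' (seed {config.seed})") from err
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        _atomic_write(out / "report.json",
                      lambda tmp: Path(tmp).write_text(json.dumps(report, indent=2)))
    return report
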
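"""Problem-container and spectrum I/O.

Problem container (HDF5, format tag ``cpprop-problem`` version 1)
-----------------------------------------------------------------
Root attributes: ``format``, ``version``, ``n_orb``, ``n_ci``, ``metadata``
(JSON string).  Datasets: ``A``, ``B``, ``Sigma``, ``Delta`` (N x N float64),
``orbital_pair_map`` (n_orb x 3 int64 rows: n, p, q), ``ci_transition_map``
(n_orb x n_ci float64), and one group per gradient at
``gradients/<operator_id>/<component>`` with datasets ``real`` and ``imag``.
Arrays round-trip bit-exactly.

Spectrum CSV columns: ``omega_eV``, ``sigma_abs``, ``sigma_disp``, then
``Re_alpha_ij``/``Im_alpha_ij`` for ij in xx, xy, ..., zz (row = A component,
column = B component).  Decomposition CSV is long format
(``p``, ``q``, ``omega_eV``, ``contribution``) where rows with p = q = -1
carry the unmapped CI residual.  A JSON sidecar records seed, options and
convergence statistics so any run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import (DimensionMismatchError, MalformedHeaderError,
                     UnsupportedVersionError)
from .problems import OperatorGradient, ResponseProblem, SolverOptions
from .properties import DecompositionReport, Spectrum

__all__ = ["write_problem", "read_problem", "write_spectrum", "read_spectrum_csv"]

FORMAT_TAG = "cpprop-problem"
FORMAT_VERSION = 1


def write_problem(path, problem: ResponseProblem) -> None:
    """Write a response problem to its HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_TAG
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["n_orb"] = problem.n_orb
        f.attrs["n_ci"] = problem.n_ci
        f.attrs["metadata"] = json.dumps(problem.metadata, default=str)
        f.create_dataset("A", data=problem.A_block)
        f.create_dataset("B", data=problem.B_block)
        f.create_dataset("Sigma", data=problem.Sigma_block)
        f.create_dataset("Delta", data=problem.Delta_block)
        f.create_dataset("orbital_pair_map", data=problem.orbital_pair_map)
        f.create_dataset("ci_transition_map", data=problem.ci_transition_map)
        for g in problem.gradients:
            grp = f.require_group(f"gradients/{g.operator_id}/{g.component}")
            grp.create_dataset("real", data=g.real_part)
            grp.create_dataset("imag", data=g.imag_part)


def read_problem(path) -> ResponseProblem:
    """Read a response problem, validating header and dimensions."""
    with h5py.File(path, "r") as f:
        if "format" not in f.attrs or "version" not in f.attrs:
            raise MalformedHeaderError(f"{path}: missing container header attributes")
        if f.attrs["format"] != FORMAT_TAG:
            raise MalformedHeaderError(f"{path}: not a {FORMAT_TAG} container")
        if int(f.attrs["version"]) != FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"{path}: unsupported container version {f.attrs['version']!r}")
        try:
            n_orb, n_ci = int(f.attrs["n_orb"]), int(f.attrs["n_ci"])
        except KeyError as exc:
            raise MalformedHeaderError(f"{path}: missing dimension attribute") from exc
        N = n_orb + n_ci
        arrays = {}
        for name in ("A", "B", "Sigma", "Delta"):
            if name not in f:
                raise MalformedHeaderError(f"{path}: missing dataset {name!r}")
            arr = f[name][...]
            if arr.shape != (N, N):
                raise DimensionMismatchError(
                    f"{path}: dataset {name} has shape {arr.shape}, expected {(N, N)}")
            arrays[name] = arr
        pm = f["orbital_pair_map"][...]
        if pm.shape != (n_orb, 3):
            raise DimensionMismatchError(
                f"{path}: orbital_pair_map shape {pm.shape} != {(n_orb, 3)}")
        T = f["ci_transition_map"][...]
        if T.shape[1] != n_ci:
            raise DimensionMismatchError(
                f"{path}: ci_transition_map has {T.shape[1]} columns, expected {n_ci}")
        gradients = []
        if "gradients" in f:
            for op_id in sorted(f["gradients"]):
                for comp in sorted(f[f"gradients/{op_id}"]):
                    grp = f[f"gradients/{op_id}/{comp}"]
                    re, im = grp["real"][...], grp["imag"][...]
                    if re.shape != (N,) or im.shape != (N,):
                        raise DimensionMismatchError(
                            f"{path}: gradient {op_id}/{comp} length != {N}")
                    gradients.append(OperatorGradient(op_id, comp, re, im))
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return ResponseProblem(n_orb=n_orb, n_ci=n_ci,
                           A_block=arrays["A"], B_block=arrays["B"],
                           Sigma_block=arrays["Sigma"], Delta_block=arrays["Delta"],
                           gradients=gradients, orbital_pair_map=pm,
                           ci_transition_map=T, metadata=metadata)


_ALPHA_COLS = [f"{ri}_alpha_{a}{b}" for ri in ("Re", "Im") for a in "xyz" for b in "xyz"]


def write_spectrum(prefix, spectrum: Spectrum,
                   decomposition: DecompositionReport | None = None,
                   options: SolverOptions | None = None,
                   extra_metadata: dict | None = None) -> list[Path]:
    """Write spectrum CSV, optional decomposition CSV, and a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    data = {"omega_eV": spectrum.omegas,
            "sigma_abs": spectrum.sigma_abs,
            "sigma_disp": spectrum.sigma_disp}
    flat = spectrum.alpha.reshape(spectrum.omegas.size, -1)
    for k, col in enumerate(_ALPHA_COLS[:9]):
        data[col] = flat[:, k].real
    for k, col in enumerate(_ALPHA_COLS[9:]):
        data[col] = flat[:, k].imag
    if spectrum.G_prime is not None:
        gflat = spectrum.G_prime.reshape(spectrum.omegas.size, -1)
        for k, (a, b) in enumerate([(a, b) for a in "xyz" for b in "xyz"]):
            data[f"Re_Gprime_{a}{b}"] = gflat[:, k].real
            data[f"Im_Gprime_{a}{b}"] = gflat[:, k].imag
    spec_path = prefix.with_name(prefix.name + "_spectrum.csv")
    pd.DataFrame(data).to_csv(spec_path, index=False)
    written.append(spec_path)

    if decomposition is not None and (decomposition.contributions
                                      or decomposition.ci_mapped):
        rows = []
        keys = sorted(set(decomposition.contributions) | set(decomposition.ci_mapped))
        for (p, q) in keys:
            contrib = (np.asarray(decomposition.contributions.get((p, q), 0.0))
                       + np.asarray(decomposition.ci_mapped.get((p, q), 0.0)))
            contrib = np.broadcast_to(contrib, decomposition.omegas.shape)
            for w, c in zip(decomposition.omegas, contrib):
                rows.append((p, q, w, c))
        for w, c in zip(decomposition.omegas, decomposition.unmapped_ci):
            rows.append((-1, -1, w, c))
        dec_path = prefix.with_name(prefix.name + "_decomposition.csv")
        pd.DataFrame(rows, columns=["p", "q", "omega_eV", "contribution"]).to_csv(
            dec_path, index=False)
        written.append(dec_path)

    meta = dict(spectrum.metadata)
    if options is not None:
        opt = dataclasses.asdict(options)
        opt["ci_reference"] = None if options.ci_reference is None else "custom"
        meta["options"] = opt
    if extra_metadata:
        meta.update(extra_metadata)
    meta["gauge"] = spectrum.gauge
    meta_path = prefix.with_name(prefix.name + "_run.json")
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    written.append(meta_path)
    return written


def read_spectrum_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
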
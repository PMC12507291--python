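"""HDF5 containers for movies, banks, TRF surfaces and responses."""

from __future__ import annotations

import numpy as np
import h5py

from .exceptions import SchemaError
from .normalization import NormalizationSpec, NormalizedResponse
from .spatial import BankSpec, LogGaborBank, LogGaborKernel
from .stimulus import RetinalMovie
from .temporal import TRFSurface

SCHEMA_VERSION = 1

__all__ = [
    "save_movie", "load_movie",
    "save_bank", "load_bank",
    "save_surface", "load_surface",
    "save_response", "load_response",
]


def _stamp(group, kind: str):
    group.attrs["schema_version"] = SCHEMA_VERSION
    group.attrs["kind"] = kind


def _check(group, kind: str):
    v = group.attrs.get("schema_version")
    if v is None or group.attrs.get("kind") != kind:
        raise SchemaError(f"container is not a streakvision {kind!r} file")
    if int(v) != SCHEMA_VERSION:
        raise SchemaError(f"schema version {v} unsupported "
                          f"(expected {SCHEMA_VERSION})")


def save_movie(path, movie: RetinalMovie, gaze=None, target=None, meta=None):
    with h5py.File(path, "w") as f:
        _stamp(f, "retinal_movie")
        f.create_dataset("movie", data=movie.frames)
        f["movie"].attrs["units"] = "Michelson contrast"
        f.attrs["pitch_dva_per_px"] = movie.pitch
        f.attrs["rate_hz"] = movie.rate
        f.attrs["extent_dva"] = movie.extent
        if gaze is not None:
            f.create_dataset("gaze", data=gaze)
            f["gaze"].attrs["units"] = "dva"
        if target is not None:
            f.create_dataset("target", data=target)
            f["target"].attrs["units"] = "dva"
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_movie(path) -> RetinalMovie:
    with h5py.File(path, "r") as f:
        _check(f, "retinal_movie")
        return RetinalMovie(frames=f["movie"][()],
                            pitch=float(f.attrs["pitch_dva_per_px"]),
                            rate=float(f.attrs["rate_hz"]),
                            extent=tuple(f.attrs["extent_dva"]))


def save_bank(path, bank: LogGaborBank):
    with h5py.File(path, "w") as f:
        _stamp(f, "log_gabor_bank")
        f.attrs["pitch_dva_per_px"] = bank.pitch
        f.attrs["sf_set_cpd"] = bank.sf_set
        f.attrs["ori_set_deg"] = bank.ori_set
        f.attrs["theta0"] = bank.spec.theta0
        f.attrs["w0"] = bank.spec.w0
        f.attrs["beta0"] = bank.spec.beta0
        for (theta, omega), k in bank.kernels.items():
            g = f.create_group(f"kernel/{theta:g}/{omega:g}")
            g.create_dataset("weights", data=k.weights)
            g.attrs["sigma_theta_oct"] = k.sigma_theta
            g.attrs["sigma_omega_deg"] = k.sigma_omega


def load_bank(path) -> LogGaborBank:
    with h5py.File(path, "r") as f:
        _check(f, "log_gabor_bank")
        spec = BankSpec(sf_set=tuple(f.attrs["sf_set_cpd"]),
                        ori_set=tuple(f.attrs["ori_set_deg"]),
                        theta0=float(f.attrs["theta0"]),
                        w0=float(f.attrs["w0"]),
                        beta0=float(f.attrs["beta0"]))
        pitch = float(f.attrs["pitch_dva_per_px"])
        kernels = {}
        for theta in spec.sf_set:
            for omega in spec.ori_set:
                g = f[f"kernel/{theta:g}/{omega:g}"]
                kernels[(theta, omega)] = LogGaborKernel(
                    theta=theta, omega=omega,
                    sigma_theta=float(g.attrs["sigma_theta_oct"]),
                    sigma_omega=float(g.attrs["sigma_omega_deg"]),
                    pitch=pitch, weights=g["weights"][()])
        return LogGaborBank(spec, pitch, kernels)


def save_surface(path, surface: TRFSurface, params_by_sf=None, meta=None):
    with h5py.File(path, "w") as f:
        _stamp(f, "trf_surface")
        f.attrs["n_pieces"] = len(surface.pieces)
        for i, p in enumerate(surface.pieces):
            g = f.create_group(f"piece/{i}")
            tx, ty, c, kx, ky = p.tck
            g.create_dataset("tck/tx", data=tx)
            g.create_dataset("tck/ty", data=ty)
            g.create_dataset("tck/c", data=c)
            g.attrs["kx"] = kx
            g.attrs["ky"] = ky
            at, ac, ak = p.amp_tck
            g.create_dataset("amp_tck/t", data=at)
            g.create_dataset("amp_tck/c", data=ac)
            g.attrs["amp_k"] = ak
            g.attrs["sf_lo_log10"] = p.sf_lo
            g.attrs["sf_hi_log10"] = p.sf_hi
        f.attrs["t_max_s"] = surface.t_max
        f.attrs["sf_range_cpd"] = surface.sf_range
        f.attrs["beta_ps"] = surface.beta_ps
        if params_by_sf is not None:
            rec = np.array([(p.A, p.tau, p.n, p.B, p.k)
                            for p in params_by_sf],
                           dtype=[("A", "f8"), ("tau", "f8"), ("n", "i4"),
                                  ("B", "f8"), ("k", "i4")])
            f.create_dataset("params_by_sf", data=rec)
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_surface(path) -> TRFSurface:
    from .temporal import SurfacePiece

    with h5py.File(path, "r") as f:
        _check(f, "trf_surface")
        pieces = []
        for i in range(int(f.attrs["n_pieces"])):
            g = f[f"piece/{i}"]
            tck = (g["tck/tx"][()], g["tck/ty"][()], g["tck/c"][()],
                   int(g.attrs["kx"]), int(g.attrs["ky"]))
            amp_tck = (g["amp_tck/t"][()], g["amp_tck/c"][()],
                       int(g.attrs["amp_k"]))
            pieces.append(SurfacePiece(sf_lo=float(g.attrs["sf_lo_log10"]),
                                       sf_hi=float(g.attrs["sf_hi_log10"]),
                                       tck=tck, amp_tck=amp_tck))
        return TRFSurface(pieces=pieces,
                          t_max=float(f.attrs["t_max_s"]),
                          sf_range=tuple(f.attrs["sf_range_cpd"]),
                          beta_ps=float(f.attrs["beta_ps"]))


def save_response(path, resp: NormalizedResponse):
    with h5py.File(path, "w") as f:
        _stamp(f, "normalized_response")
        f.create_dataset("R_N", data=resp.rn)
        if resp.re is not None:
            f.create_dataset("R_E", data=resp.re)
        if resp.rlp is not None:
            f.create_dataset("R_LP", data=resp.rlp)
        f.attrs["sf_set_cpd"] = resp.sf_set
        f.attrs["ori_set_deg"] = resp.ori_set
        f.attrs["rate_hz"] = resp.rate
        f.attrs["pitch_dva_per_px"] = resp.pitch
        f.attrs["extent_dva"] = resp.extent
        spec = resp.spec or NormalizationSpec()
        for name in ("tau_n", "gl_sd", "sigma_semi", "exponent",
                     "pool_radius", "sigma_p_theta", "sigma_p_omega"):
            f.attrs[f"norm_{name}"] = getattr(spec, name)


def load_response(path) -> NormalizedResponse:
    with h5py.File(path, "r") as f:
        _check(f, "normalized_response")
        spec = NormalizationSpec(
            tau_n=float(f.attrs["norm_tau_n"]),
            gl_sd=float(f.attrs["norm_gl_sd"]),
            sigma_semi=float(f.attrs["norm_sigma_semi"]),
            exponent=float(f.attrs["norm_exponent"]),
            pool_radius=int(f.attrs["norm_pool_radius"]),
            sigma_p_theta=float(f.attrs["norm_sigma_p_theta"]),
            sigma_p_omega=float(f.attrs["norm_sigma_p_omega"]))
        return NormalizedResponse(
            rn=f["R_N"][()],
            re=f["R_E"][()] if "R_E" in f else None,
            rlp=f["R_LP"][()] if "R_LP" in f else None,
            sf_set=f.attrs["sf_set_cpd"][()],
            ori_set=f.attrs["ori_set_deg"][()],
            rate=float(f.attrs["rate_hz"]),
            pitch=float(f.attrs["pitch_dva_per_px"]),
            extent=tuple(f.attrs["extent_dva"]), spec=spec)
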
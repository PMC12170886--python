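"""SPR sensorgram processing and steady-state 1:1 affinity analysis.

A multi-cycle kinetics experiment injects an analyte dilution series over an
immobilised ligand.  Double referencing subtracts a reference flow cell and
a zero-concentration (blank) cycle to remove bulk and drift artefacts.  The
equilibrium response per concentration, read at the end of the association
phase, follows the 1:1 Langmuir isotherm

    Req(C) = Rmax * C / (KD + C)

fitted here by nonlinear least squares.  By construction Req(KD) = Rmax/2,
so KD can also be read off as the concentration at half-maximal response.
Fragment-inhibition experiments are quantified as the percentage reduction
of the analyte binding response after pre-incubation with the fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class Sensorgram:
    """One SPR cycle: time series of response at a fixed analyte concentration."""

    cycle_id: str
    concentration_nM: float
    time_s: np.ndarray
    response_RU: np.ndarray
    association_start_s: float = 0.0
    association_end_s: float = 600.0
    dissociation_end_s: float = 900.0
    flow_cell: str = "active"
    double_referenced: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_RU = np.asarray(self.response_RU, dtype=float)
        if len(self.time_s) != len(self.response_RU):
            raise ValueError("time and response lengths differ")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration_nM < 0:
            raise ValueError("concentration must be >= 0")
        if not (
            self.association_start_s <= self.association_end_s <= self.dissociation_end_s
        ):
            raise ValueError("phase boundaries out of order")


@dataclass
class SteadyStateFit:
    kd_nM: float
    rmax_RU: float
    rss: float
    req_by_conc: dict[float, float]
    converged: bool
    censored: bool = False

    def response_at(self, conc_nM: float) -> float:
        return self.rmax_RU * conc_nM / (self.kd_nM + conc_nM)


@dataclass
class InhibitionResult:
    fragment_id: str
    response_alone_RU: float
    response_with_RU: float
    percent_inhibition: float


def _interp_to(grid: np.ndarray, sg: Sensorgram) -> np.ndarray:
    return np.interp(grid, sg.time_s, sg.response_RU)


def double_reference(
    active: Sensorgram,
    reference: Sensorgram,
    blank_active: Sensorgram | None = None,
    blank_reference: Sensorgram | None = None,
) -> Sensorgram:
    """(active − reference) − (blank_active − blank_reference), baseline-zeroed.

    The reference-cell subtraction removes bulk refractive-index and drift
    components common to both flow cells; the blank-cycle subtraction removes
    systematic injection artefacts.  Missing blank cycles yield a
    single-referenced output flagged as such.  The pre-injection mean is
    subtracted as baseline.
    """
    grid = active.time_s
    corrected = active.response_RU - _interp_to(grid, reference)
    flags = []
    if blank_active is not None:
        blank = _interp_to(grid, blank_active)
        if blank_reference is not None:
            blank = blank - _interp_to(grid, blank_reference)
        corrected = corrected - blank
    else:
        flags.append("single_referenced")
    pre = grid < active.association_start_s
    if pre.any():
        corrected = corrected - corrected[pre].mean()
    return Sensorgram(
        cycle_id=active.cycle_id,
        concentration_nM=active.concentration_nM,
        time_s=grid,
        response_RU=corrected,
        association_start_s=active.association_start_s,
        association_end_s=active.association_end_s,
        dissociation_end_s=active.dissociation_end_s,
        flow_cell="corrected",
        double_referenced=blank_active is not None,
        flags=flags,
    )


def steady_state_response(
    sensorgram: Sensorgram, window_s: float = 5.0, slope_tol_RU_per_s: float = 0.1
) -> tuple[float, bool]:
    """Mean response over the final window of the association phase.

    Returns (Req, equilibrated); equilibrated is False when the response is
    still rising faster than ``slope_tol_RU_per_s`` inside the window,
    indicating kinetics too slow for the injection length (Req then
    underestimates true equilibrium).
    """
    t0, t1 = sensorgram.association_start_s, sensorgram.association_end_s
    if window_s > t1 - t0:
        raise ValueError("window longer than association phase")
    mask = (sensorgram.time_s >= t1 - window_s) & (sensorgram.time_s <= t1)
    if not mask.any():
        raise ValueError("no samples inside steady-state window")
    t = sensorgram.time_s[mask]
    r = sensorgram.response_RU[mask]
    req = float(r.mean())
    equilibrated = True
    if len(t) >= 2 and np.ptp(t) > 0:
        slope = float(np.polyfit(t, r, 1)[0])
        equilibrated = abs(slope) <= slope_tol_RU_per_s
    return req, equilibrated


def langmuir_isotherm(conc_nM: np.ndarray, kd_nM: float, rmax_RU: float) -> np.ndarray:
    return rmax_RU * np.asarray(conc_nM, dtype=float) / (kd_nM + np.asarray(conc_nM, dtype=float))


def fit_steady_state(concentrations_nM: np.ndarray, req_RU: np.ndarray) -> SteadyStateFit:
    """Nonlinear least-squares fit of the 1:1 steady-state isotherm.

    Initialised at Rmax0 = 1.1*max(Req) and KD0 = concentration nearest
    half-max; bounded KD in (0, 100*Cmax], Rmax in (0, 10*max(Req)].  When
    the data show no curvature (Req effectively proportional to C) the KD is
    reported censored at its upper bound with converged=False.
    """
    conc = np.asarray(concentrations_nM, dtype=float)
    req = np.asarray(req_RU, dtype=float)
    mask = conc > 0
    conc, req = conc[mask], req[mask]
    if len(np.unique(conc)) < 3:
        raise ValueError("need >= 3 distinct non-zero concentrations")
    req_by_conc = {float(c): float(r) for c, r in zip(conc, req)}
    rmax_max = float(req.max())
    if rmax_max <= 0:
        return SteadyStateFit(float("nan"), float("nan"), float("nan"), req_by_conc, False)
    rmax0 = 1.1 * rmax_max
    kd0 = float(conc[np.argmin(np.abs(req - rmax_max / 2.0))])
    cmax = float(conc.max())
    try:
        popt, _ = curve_fit(
            langmuir_isotherm,
            conc,
            req,
            p0=[kd0, rmax0],
            bounds=([1e-12, 1e-12], [100.0 * cmax, 10.0 * rmax_max]),
            maxfev=10000,
        )
    except RuntimeError:
        return SteadyStateFit(float("nan"), float("nan"), float("nan"), req_by_conc, False)
    kd, rmax = float(popt[0]), float(popt[1])
    rss = float(((langmuir_isotherm(conc, kd, rmax) - req) ** 2).sum())
    # with no curvature only the ratio Rmax/KD is identifiable and the fit
    # pins one parameter at its bound; report KD as lower-bound censored
    censored = kd >= 0.99 * 100.0 * cmax or rmax >= 0.99 * 10.0 * rmax_max
    return SteadyStateFit(kd, rmax, rss, req_by_conc, converged=not censored, censored=censored)


def kd_from_half_max(concentrations_nM: np.ndarray, req_RU: np.ndarray, rmax_RU: float) -> float:
    """Half-max reading of KD: concentration where Req crosses Rmax/2 (log-interp)."""
    conc = np.asarray(concentrations_nM, dtype=float)
    req = np.asarray(req_RU, dtype=float)
    order = np.argsort(conc)
    conc, req = conc[order], req[order]
    half = rmax_RU / 2.0
    if req.max() < half:
        raise ValueError("response never reaches half of Rmax")
    return float(np.interp(half, req, conc))


def percent_inhibition(response_alone_RU: float, response_with_RU: float) -> float:
    """100·(1 − with/alone); negative values indicate enhancement, not clamped."""
    if response_alone_RU <= 0:
        raise ValueError("response_alone must be > 0")
    return 100.0 * (1.0 - response_with_RU / response_alone_RU)


def inhibition_table(
    response_alone_RU: float, responses_with: dict[str, float]
) -> list[InhibitionResult]:
    return [
        InhibitionResult(frag, response_alone_RU, resp, percent_inhibition(response_alone_RU, resp))
        for frag, resp in responses_with.items()
    ]


def serial_dilution(top: float, factor: float, n_points: int) -> list[float]:
    """Descending dilution series [top, top/factor, ..., top/factor^(n-1)]."""
    if top <= 0 or factor <= 1 or n_points < 1:
        raise ValueError("need top > 0, factor > 1, n_points >= 1")
    return [top / factor**i for i in range(n_points)]
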
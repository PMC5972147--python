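"""Nested ODE models of the TGF-beta -> SMAD / GLI1 / GSK3 -> SNAIL1 network.

Three variants share one right-hand side, gated by structural flags so the
nesting SMAD_ONLY < SMAD_GLI < FULL holds by construction:

* ``SMAD_ONLY`` — canonical pathway: TGF-beta phosphorylates SMAD2/3, the
  nuclear pSMAD complex transactivates SNAIL1 and I-SMAD, and I-SMAD closes
  a negative feedback that makes the pSMAD response transient.
* ``SMAD_GLI`` — adds the GLI1 branch: pSMAD-driven GLI1 transcription, a
  GLI1 transcriptional positive feedback, a SUFU-bound inactive cytosolic
  pool, release to free GLI1 and nuclear import.  GSK3 activity is frozen
  at its basal value.
* ``FULL`` — adds the GSK3 phosphorylation switch: total GSK3 (normalized
  to 1) partitions into unphosphorylated-active A, tyrosine-phosphorylated
  extra-active AA (ER/Golgi-localized) and serine-phosphorylated inactive
  D, with TGF-beta driving transient A->AA and slower A->D conversion.
  GSK3^AA boosts the SUFU-complex release flux (its ER/Golgi role); active
  GSK3 catalyzes degradation of SNAIL1 protein and the GLI1 pools.

State layout (fixed length 18; unused entries stay zero):
``R, I, Sm, Sp, Gm, Gb, Gf, Gn, AA, D, c1..c6, s1, P`` where c1–c6 is a
linear filter cascade generating the band-pass "localization" signal of
the GSK3^AA transient and s1 the slow filter driving A->D conversion.
The basal A->AA flux saturates in A (Michaelis constant 0.02), reflecting
the observation that total GSK3^AA abundance stays stable while the D
fraction grows; the transient-bump flux is mass-action in A.  P is a
slowly decaying persistent-signaling pool (internalized active receptor
complexes and induced autocrine ligand) charged by exogenous ligand
exposure; it adds to the stimulus in the SMAD phosphorylation flux, so
washed-out pulses leave a duration-graded pSMAD residue while a
receptor-kinase inhibitor silences both inputs at once.
GSK3_A is eliminated algebraically (A = 1 - AA - D), so the conservation
law holds to machine precision along every trajectory.

Degradation rates are parameterized around the basal point: e.g. SNAIL1
protein decays at ``d_Sp * (eps_Sp + (1-eps_Sp) * m_nuc * g_k * A/A_b)``,
which equals ``d_Sp`` exactly at basal GSK3 activity, so ``d_Sp`` is the
observable basal turnover and ``eps_Sp`` its GSK3-independent share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import PARAM_NAMES, ParameterSet

NSTATE = 18
#: indices into the state vector
IR, II, ISM, ISP, IGM, IGB, IGF, IGN, IAA, ID_ = range(10)
IC1, IC6, IS1, IPER = 10, 15, 16, 17

#: peak of (t/tau)^5 e^(-t/tau)/5! for a unit step — normalizes the
#: band-pass filter output so 'bump' peaks near 1 under amplitude-1 input.
BUMP_NORM = 5.0 ** 5 * np.exp(-5.0) / 120.0
#: Michaelis constant of the basal (co-translational) A->AA flux
K_SAT_A = 0.02

VARIANTS = ("SMAD_ONLY", "SMAD_GLI", "FULL")

_SPECIES = {
    "SMAD_ONLY": ("pSMAD_nuc", "ISMAD", "SNAIL1_mRNA", "SNAIL1_prot"),
    "SMAD_GLI": ("pSMAD_nuc", "ISMAD", "SNAIL1_mRNA", "SNAIL1_prot",
                  "GLI1_mRNA", "GLI1_bound", "GLI1_free", "GLI1_nuc"),
    "FULL": ("pSMAD_nuc", "ISMAD", "SNAIL1_mRNA", "SNAIL1_prot",
              "GLI1_mRNA", "GLI1_bound", "GLI1_free", "GLI1_nuc",
              "GSK3_A", "GSK3_AA", "GSK3_D"),
}

#: state index of each reported species; GSK3_A is derived (A = 1 - AA - D)
SPECIES_STATE_INDEX = {
    "pSMAD_nuc": IR, "ISMAD": II, "SNAIL1_mRNA": ISM, "SNAIL1_prot": ISP,
    "GLI1_mRNA": IGM, "GLI1_bound": IGB, "GLI1_free": IGF, "GLI1_nuc": IGN,
    "GSK3_A": -1, "GSK3_AA": IAA, "GSK3_D": ID_,
}

_SMAD_PARAMS = ("b_R", "k_R", "K_IR", "d_R", "b_I", "k_I", "K_RI", "d_I",
                "k_per", "K_per", "r_per",
                "b_S", "a_SR", "K_SR", "d_Sm", "k_tp", "d_Sp", "eps_Sp")
_GLI_PARAMS = ("a_SG", "K_SG", "n_SG", "b_G", "a_GR", "K_GR", "a_GG", "K_GG", "n_GG",
               "d_Gm", "k_tg", "rho0", "rho1", "k_in", "d_Gc", "eps_G",
               "d_Gn", "eps_Gn")
_GSK_PARAMS = ("f_aa_b", "f_d_b", "r_aa", "k_aa", "tau_b", "r_d", "k_d",
               "tau_d", "lam_loc", "m_nuc", "m_cyt")

_EDGES_SMAD = (
    ("TGFb", "pSMAD_nuc", "+"),
    ("pSMAD_nuc", "TGFb_persistent", "+"),  # autocrine/internalized signaling
    ("TGFb_persistent", "pSMAD_nuc", "+"),
    ("pSMAD_nuc", "ISMAD", "+"),
    ("ISMAD", "pSMAD_nuc", "-"),
    ("pSMAD_nuc", "SNAIL1_mRNA", "+"),
    ("SNAIL1_mRNA", "SNAIL1_prot", "+"),
    ("others", "SNAIL1_mRNA", "+"),
)
_EDGES_GLI = (
    ("pSMAD_nuc", "GLI1_mRNA", "+"),
    ("GLI1_nuc", "GLI1_mRNA", "+"),   # transcriptional positive feedback
    ("GLI1_nuc", "SNAIL1_mRNA", "+"),
    ("GLI1_mRNA", "GLI1_bound", "+"),
    ("GLI1_bound", "GLI1_free", "+"),
    ("GLI1_free", "GLI1_nuc", "+"),
)
_EDGES_GSK = (
    ("TGFb", "GSK3_AA", "+"),
    ("TGFb", "GSK3_D", "+"),
    ("GSK3_AA", "GLI1_bound->GLI1_free", "+"),  # ER/Golgi release flux
    ("GSK3_A", "SNAIL1_prot", "-"),
    ("GSK3_A", "GLI1_bound", "-"),
    ("GSK3_A", "GLI1_free", "-"),
    ("GSK3_A", "GLI1_nuc", "-"),
)


@njit(cache=True)
def rhs_kernel(t, y, p, S, g_s, g_g, g_k, has_gli, has_gsk):  # pragma: no cover
    dy = np.zeros(NSTATE)
    R, I, Sm, Sp = y[0], y[1], y[2], y[3]
    Gm, Gb, Gf, Gn = y[4], y[5], y[6], y[7]
    AA, D = y[8], y[9]

    f_aa_b, f_d_b = p[33], p[34]
    A_b = 1.0 - f_aa_b - f_d_b

    if has_gsk:
        A = 1.0 - AA - D
        bump = y[14] - y[15]
        if bump < 0.0:
            bump = 0.0
        bump /= BUMP_NORM
        rel_A = A / A_b          # relative active-GSK3 level
        rel_AA = AA / f_aa_b     # relative extra-active level
    else:
        bump = 0.0
        rel_A = 1.0
        rel_AA = 1.0

    m_nuc, m_cyt = p[41], p[42]
    act_nuc = g_k * m_nuc * rel_A
    act_cyt = g_k * m_cyt * rel_A
    act_er = g_k * m_cyt * rel_AA * (1.0 + p[27] * bump)

    # SMAD module; the persistent pool P adds to the exogenous ligand and
    # is silenced by the same receptor-kinase gate g_s
    P = y[17]
    uI = I / p[2]
    prodR = (p[0] + g_s * p[1] * (S + P)) / (1.0 + uI * uI)
    dy[0] = prodR - p[3] * R
    uR = R / p[6]
    hR_I = uR * uR / (1.0 + uR * uR)
    dy[1] = p[4] + p[5] * hR_I - p[7] * I
    dy[17] = g_s * p[43] * S * p[44] / (p[44] + P) - p[45] * P

    # SNAIL1 module
    uR = R / p[10]
    hR_S = uR * uR / (1.0 + uR * uR)
    syn_S = p[8] + p[9] * hR_S
    if has_gli:
        uG = Gn / p[12]
        syn_S += g_g * p[11] * uG ** p[46] / (1.0 + uG ** p[46])
    dy[2] = syn_S - p[13] * Sm
    eps_Sp = p[16]
    dy[3] = p[14] * Sm - p[15] * (eps_Sp + (1.0 - eps_Sp) * act_nuc) * Sp

    if has_gli:
        uR = R / p[19]
        hR_G = uR * uR / (1.0 + uR * uR)
        uG = Gn / p[21]
        hG = uG ** p[22] / (1.0 + uG ** p[22])
        dy[4] = p[17] + p[18] * hR_G + g_g * p[20] * hG - p[23] * Gm
        rel = p[25] + p[26] * act_er
        eps_G = p[30]
        deg_c = p[29] * (eps_G + (1.0 - eps_G) * act_cyt)
        dy[5] = p[24] * Gm - rel * Gb - deg_c * Gb
        dy[6] = rel * Gb - p[28] * Gf - deg_c * Gf
        eps_Gn = p[32]
        dy[7] = p[28] * Gf - p[31] * (eps_Gn + (1.0 - eps_Gn) * act_nuc) * Gn

    if has_gsk:
        A = 1.0 - AA - D
        sat_b = A_b / (K_SAT_A + A_b)
        k_aa0 = p[35] * f_aa_b / sat_b
        k_d0 = p[38] * f_d_b / A_b
        dy[8] = k_aa0 * A / (K_SAT_A + A) + p[36] * bump * A - p[35] * AA
        dy[9] = (k_d0 + p[39] * y[16]) * A - p[38] * D
        tau_b, tau_d = p[37], p[40]
        dy[10] = (S - y[10]) / tau_b
        for j in range(11, 16):
            dy[j] = (y[j - 1] - y[j]) / tau_b
        dy[16] = (S - y[16]) / tau_d
    return dy


@njit(cache=True)
def integrate_fixed(y0, edges, vals, h, t_out, has_gli, has_gsk, p):  # pragma: no cover
    """Classic RK4 with fixed step ``h``, sampling exactly at ``t_out``.

    ``edges``/``vals`` define piecewise-constant (S, gates); steps never
    straddle a segment edge or an output time.
    """
    n_out = t_out.size
    out = np.empty((n_out, NSTATE))
    y = y0.copy()
    io = 0
    t = edges[0]
    while io < n_out and t_out[io] <= t + 1e-12:
        out[io] = y
        io += 1
    for s in range(vals.shape[0]):
        t_end = edges[s + 1]
        S, g_s, g_g, g_k = vals[s, 0], vals[s, 1], vals[s, 2], vals[s, 3]
        while t < t_end - 1e-12:
            t_stop = t_end
            if io < n_out and t_out[io] < t_stop:
                t_stop = t_out[io]
            while t < t_stop - 1e-12:
                dt = h
                if t + dt > t_stop:
                    dt = t_stop - t
                k1 = rhs_kernel(t, y, p, S, g_s, g_g, g_k, has_gli, has_gsk)
                k2 = rhs_kernel(t + 0.5 * dt, y + 0.5 * dt * k1, p, S, g_s, g_g, g_k, has_gli, has_gsk)
                k3 = rhs_kernel(t + 0.5 * dt, y + 0.5 * dt * k2, p, S, g_s, g_g, g_k, has_gli, has_gsk)
                k4 = rhs_kernel(t + dt, y + dt * k3, p, S, g_s, g_g, g_k, has_gli, has_gsk)
                y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                t = t + dt
            while io < n_out and t_out[io] <= t + 1e-12:
                out[io] = y
                io += 1
    while io < n_out:  # numerical ties at the final edge
        out[io] = y
        io += 1
    return out


@dataclass(frozen=True)
class NetworkModel:
    """A model variant: species roster, structural flags, shared RHS."""

    variant: str
    species: tuple[str, ...]
    has_gli: bool
    has_gsk: bool
    param_names: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def rhs(self, t: float, y: np.ndarray, params: ParameterSet | np.ndarray,
            S: float = 0.0, g_smad: float = 1.0, g_gli: float = 1.0,
            g_gsk: float = 1.0) -> np.ndarray:
        """Evaluate the full-state right-hand side (mostly for tests)."""
        p = params.to_vector() if isinstance(params, ParameterSet) else np.asarray(params)
        return rhs_kernel(float(t), np.asarray(y, dtype=float), p, float(S),
                          float(g_smad), float(g_gli), float(g_gsk),
                          self.has_gli, self.has_gsk)

    def state_to_species(self, y: np.ndarray) -> np.ndarray:
        """Map full-state row(s) onto this variant's species columns."""
        y = np.atleast_2d(y)
        cols = []
        for name in self.species:
            idx = SPECIES_STATE_INDEX[name]
            if idx == -1:  # GSK3_A, conserved remainder
                cols.append(1.0 - y[:, IAA] - y[:, ID_])
            else:
                cols.append(y[:, idx])
        return np.column_stack(cols)


def build_model(variant: str) -> NetworkModel:
    """Construct one of the nested variants: SMAD_ONLY, SMAD_GLI or FULL."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    has_gli = variant in ("SMAD_GLI", "FULL")
    has_gsk = variant == "FULL"
    pnames = _SMAD_PARAMS
    edges = _EDGES_SMAD
    if has_gli:
        pnames = pnames + _GLI_PARAMS
        edges = edges + _EDGES_GLI
    if has_gsk:
        pnames = pnames + _GSK_PARAMS
        edges = edges + _EDGES_GSK
    # keep canonical ordering for readability
    pnames = tuple(n for n in PARAM_NAMES if n in set(pnames))
    return NetworkModel(variant=variant, species=_SPECIES[variant],
                        has_gli=has_gli, has_gsk=has_gsk,
                        param_names=pnames, edges=edges)
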
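"""Named default parameter sets for the firing phenotypes.

``short_rdp`` cells carry only the neuronal T-type/SK machinery, so the
rebound collapses within a few hundred milliseconds.  ``long_rdp`` cells
additionally couple to a glial compartment carrying a post-junctional
T-type trigger and the CNG-like plateau conductance, which sustains the
depolarization for seconds.  The HF/LF firing phenotypes differ in the
strength of the slow adaptation current.  Spontaneous-activity variants
(silent/tonic/burst) shift the leak reversal and add Ornstein-Uhlenbeck
current noise.
"""

from __future__ import annotations

from .model import ModelParams

# conductances shared by all spiking phenotypes
_SPIKE = dict(g_Na=500.0, g_K=150.0)

_RDP = {
    "short_rdp": dict(
        g_T=22.0, g_SK=1.5, g_H=0.4,
        g_T_glia=0.0, g_CNG=0.0, g_gap=0.5,
    ),
    "long_rdp": dict(
        g_T=22.0, g_SK=1.5, g_H=0.4,
        g_T_glia=40.0, g_CNG=60.0, g_SK_glia=1.5, g_gap=4.0,
        alpha_CNG=0.06,
    ),
}

_FIRING = {
    "hf": dict(g_adapt=0.5, p_Na_floor=0.85),
    "lf": dict(g_adapt=0.5, p_Na_floor=0.35),
}

# spontaneous-activity variants are defined by the target resting
# potential of the (coupled) neuron plus the OU current-noise amplitude;
# the leak reversal that realizes the target rest is solved for in
# cell_params, because the gap junction otherwise drags the neuron
# toward the glial resting potential by an amount that depends on g_gap
_SPONT = {
    "silent": dict(rest_mV=-68.0, noise_sigma=4.0),
    "tonic": dict(rest_mV=-42.0, noise_sigma=4.0),
    "burst": dict(rest_mV=-63.0, noise_sigma=20.0),
}


def cell_params(rdp_kind: str = "short_rdp", firing_kind: str = "hf",
                spont_kind: str | None = None, **overrides) -> ModelParams:
    """Assemble a :class:`ModelParams` from named phenotype components."""
    if rdp_kind not in _RDP:
        raise ValueError(f"unknown RDP phenotype {rdp_kind!r}")
    if firing_kind not in _FIRING:
        raise ValueError(f"unknown firing phenotype {firing_kind!r}")
    kw = {**_SPIKE, **_RDP[rdp_kind], **_FIRING[firing_kind]}
    rest_mV = None
    if spont_kind is not None:
        if spont_kind not in _SPONT:
            raise ValueError(f"unknown spontaneous phenotype {spont_kind!r}")
        spont = dict(_SPONT[spont_kind])
        rest_mV = spont.pop("rest_mV")
        kw.update(spont)
    kw.update(overrides)
    p = ModelParams(**kw)
    if rest_mV is not None and "E_leak_n" not in overrides:
        from .model import _glial_rest

        v_g = _glial_rest(p, rest_mV)
        e_leak = rest_mV + p.g_gap * (rest_mV - v_g) / p.g_leak_n
        p = p.replace(E_leak_n=e_leak)
    return p


def short_rdp(**overrides) -> ModelParams:
    return cell_params("short_rdp", "hf", **overrides)


def long_rdp(**overrides) -> ModelParams:
    return cell_params("long_rdp", "hf", **overrides)


def defaults() -> dict:
    """All named phenotype parameter sets, fully resolved."""
    out = {}
    for rdp in _RDP:
        for firing in _FIRING:
            out[f"{rdp}&{firing}"] = cell_params(rdp, firing)
    return out
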
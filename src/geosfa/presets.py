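"""Named model presets: the seven spatial-structure variants, the two
alternative input notions, and the robustness battery — all expressed
purely as :class:`~geosfa.model.ModelSpec` configuration.

Models 12-15 are covariate recodings: they reference alternative
inefficiency-covariate columns (for example a stroke-unit indicator at
a different procedure threshold, certificate-age splits, or extra
district-level health covariates) that the supplied panel must contain
under the listed names; no dedicated code path exists or is needed.
"""

from __future__ import annotations

from .model import EQ7_COVARIATES, ModelSpec


def _cov(*, drop=(), add=(), replace=None) -> list:
    cov = [c for c in EQ7_COVARIATES if c not in drop]
    if replace:
        cov = [replace.get(c, c) for c in cov]
    return cov + list(add)


def get_preset(name: str, **overrides) -> ModelSpec:
    """Return a fresh ModelSpec for a named preset; keyword overrides
    are applied on top (for example reduced MCMC settings)."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_BUILDERS)}")
    spec = _BUILDERS[name]()
    return spec.with_updates(**overrides) if overrides else spec


def preset_names() -> list:
    return sorted(_BUILDERS)


_BUILDERS = {
    # -- spatial-structure suite (model-selection table)
    "model1": lambda: ModelSpec(name="model1", struct_level=None,
                                unstruct_level=None, hospital_effect=True),
    "model2": lambda: ModelSpec(name="model2"),
    "model3": lambda: ModelSpec(name="model3", unstruct_level=None),
    "model4": lambda: ModelSpec(name="model4", struct_level=None),
    "model5": lambda: ModelSpec(name="model5", struct_level="coarse",
                                unstruct_level="coarse"),
    "model6": lambda: ModelSpec(name="model6", struct_level="coarse",
                                unstruct_level=None),
    "model7": lambda: ModelSpec(name="model7", struct_level=None,
                                unstruct_level="coarse"),
    # -- alternative performance notions
    "model8": lambda: ModelSpec(name="model8", frontier_inputs="quality_only",
                                ineff_covariates=_cov(add=("log_phys",
                                                           "log_nurse"))),
    "model9": lambda: ModelSpec(name="model9", frontier_inputs="resource_only",
                                ineff_covariates=_cov(
                                    add=("D_mor", "D_readm", "log_mor_star",
                                         "log_readm_star"))),
    # -- robustness battery
    "model10": lambda: ModelSpec(name="model10", functional_form="translog"),
    "model11": lambda: ModelSpec(name="model11"),  # + zero_mode=rescale_half
    "model12": lambda: ModelSpec(name="model12", ineff_covariates=_cov(
        replace={"SUnonCert": "SUnonCert5"})),
    "model13": lambda: ModelSpec(name="model13", ineff_covariates=_cov(
        replace={"SUnonCert": "SUnonCert20"})),
    "model14": lambda: ModelSpec(name="model14", ineff_covariates=_cov(
        drop=("SUCert",), add=("SUCertYoung", "SUCertOld"))),
    "model15": lambda: ModelSpec(name="model15", ineff_covariates=_cov(
        add=("log_MortalityDis", "log_PopageDis", "log_UnemplrateDis",
             "log_GDPpCapDis"))),
    "model16": lambda: ModelSpec(name="model16", struct_level="district",
                                 unstruct_level="coarse"),
    "model17": lambda: ModelSpec(name="model17", struct_level="coarse",
                                 unstruct_level="district"),
}

#: zero-input handling per preset where it deviates from the default
ZERO_MODE = {"model11": "rescale_half"}


def zero_mode_for(name: str) -> str:
    return ZERO_MODE.get(name, "dummy")
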
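"""spinefe: desk-scale nonlinear finite elements for spine biomechanics.

Subpackages
-----------
mesh        structured primitives, conformal node-merging, geometric audits
materials   isotropic elastic and quasi-incompressible neo-Hookean laws
cavity      hydrostatic fluid-cavity elements (shared pressure unknown)
engine      quasi-static nonlinear solver and result extractors
anatomy     parametric synthetic torso assemblies and tissue tables
experiments validation tests and sensitivity studies (CLI surface)
"""

from . import cavity, engine, io, materials, mesh  # noqa: F401

def __getattr__(name):  # anatomy/experiments import lazily (they are heavier)
    if name in ("anatomy", "experiments"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)


__version__ = "0.1.0"
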
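"""In vitro actin motility assay analysis and simulation.

Subpackages cover the full computational chain of a gliding-filament
motility experiment: synthesis of ground-truth mock videos
(:mod:`~actomotility.mockvideo`), automated filament tracking and
kinematics (:mod:`~actomotility.videoanalysis`), machine-learning trace
quality control (:mod:`~actomotility.traceqc`), length-resolved motility
features with bootstrap confidence bands (:mod:`~actomotility.features`),
bootstrapped-PCA condition statistics (:mod:`~actomotility.stats`), and a
stochastic simulator of mechanically coupled myosins propelling actin
(:mod:`~actomotility.motorsim`).
"""

__version__ = "0.1.0"

from . import features, motorsim  # noqa: F401

__all__ = [
    "features", "motorsim", "mockvideo", "videoanalysis", "traceqc",
    "stats", "pipeline", "store", "__version__",
]


def __getattr__(name):
    # image/statistics modules import scikit-image and scikit-learn;
    # load them lazily so simulation-only use stays light
    if name in __all__:
        import importlib
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
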
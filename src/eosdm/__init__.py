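"""eosdm: random-forest species distribution modelling from Earth-observation
proxy variables and small-mammal field surveys.

The package covers the full workflow: synthetic landscape/scene/survey
generation with known ground truth, the spectral-index suite and tasselled
cap, temporal percentile composites, random-forest land cover with focal
class proportions, trapline/transect abundance indices (Poisson GLMM with
effort offset), Boruta all-relevant feature selection, and a tuned
random-forest abundance SDM with leave-one-out validation and mean-threshold
optimal-habitat mapping.
"""

from .grid import GridSpec, Raster
from .scene import Scene
from . import autocorr, boruta, composites, glmm, indices, io, landcover, pipeline, sdm, survey, synthetic

__version__ = "0.1.0"

__all__ = [
    "GridSpec",
    "Raster",
    "Scene",
    "autocorr",
    "boruta",
    "composites",
    "glmm",
    "indices",
    "io",
    "landcover",
    "pipeline",
    "sdm",
    "survey",
    "synthetic",
]
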
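"""oftphase: phase-spectral analysis of optical-fiber-tweezers
back-scattering signals.

The package turns raw back-scattering voltage recordings (or synthetic
stand-ins) into phase-derived feature tables and screens every feature for
class discrimination with nonparametric tests. See :mod:`oftphase.pipeline`
for the end-to-end entry point and the command-line interface in
:mod:`oftphase.cli`.
"""

from .exceptions import (ConfigurationError, DataError, FormatError,
                         OftPhaseError)
from .features import build_feature_table, coefficient_features, descriptive_features
from .io import (Acquisition, Dataset, Epoch, PhaseMethod,
                 PhaseRepresentation, read_acquisition, write_acquisition,
                 write_results)
from .phase import (AnalyticSignal, analytic_signal, dft_phase,
                    extract_representation, hilbert_phase, phase_slope,
                    unwrap, wrap)
from .pipeline import PipelineResult, RunConfig, make_report, run_pipeline
from .preprocess import (FilterSpec, apply_highpass, design_highpass,
                         segment_epochs, zscore_reject)
from .simulate import (ClassTemplate, StudyDesign, four_class_design,
                       simulate_acquisition, simulate_dataset)
from .stats import (StatReport, TestResult, check_assumptions,
                    kruskal_wallis, mann_whitney, screen_features)
from .surrogate import (SurrogateReport, iaaft_surrogate,
                        phase_randomized_surrogate, surrogate_validation)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
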
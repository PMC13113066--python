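"""boarscan: scanning-factor analysis for image-based boar semen-quality prediction.

The package simulates testicular B-mode-like ultrasound data with a planted
class signal, labels boars from longitudinal semen records by a two-step
rule, evaluates image classifiers under subject-level (By-ID) 5-fold
cross-validation with boar-level probability aggregation, and quantifies
the influence of four scanning/processing factors (region, angle,
augmentation, model capacity) with factorial ANOVA and OLS.
"""

from . import augment, evaluation, harness, labeling, stats, synthetic
from .augment import (AugmentationGroup, AugmentationParams, apply_brightness,
                      apply_morphological, build_pipeline, comprehensive_group,
                      crop_region, morphological_group)
from .evaluation import (BoarPrediction, MetricSet, RunResult, aggregate,
                         evaluate_config, metrics_from_counts, score)
from .harness import (ClassifierSpec, SplitAssignment, TrainedModel,
                      by_id_kfold, extract_features, predict_proba, train)
from .labeling import (BoarLabel, CollectionStatus, classify_collection,
                       good_count, label_boar, label_dataset)
from .stats import (EstimabilityError, LinearModelReport, ScanConfig,
                    all_configs, condition_number, durbin_watson,
                    fit_main_effects, fit_two_way, run_grid,
                    simulate_factor_responses)
from .synthetic import (BoarProfile, Dataset, GeneratorParams, SemenRecord,
                        UltrasoundImage, make_dataset, read_dataset,
                        render_image, simulate_population,
                        simulate_semen_history, write_dataset)

__version__ = "0.1.0"
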
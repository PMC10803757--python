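"""Generate the default synthetic cohort and persist it with its ground truth.

Writes beta matrix, sample sheet, probe annotation, detection p-values and
the planted-effect record to results/cohort/.  The cohort mirrors the study
design: 35 exposed / 47 control newborns, term gestational ages, a planted
epigenetic-GA deceleration in the exposed group, group-shifted cell
composition, four group-shifted epigenetic-score panels, and BDNF negatively
coupled to the planted acceleration.
"""

import pathlib

import cordmeth as cm
import cordmeth.io as cio
from cordmeth.synthetic import DEFAULT_CELL_TYPES, SimulationConfig

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    clock = cm.make_toy_clock(config.n_clock_probes, seed=SEED)
    reference = cm.make_cell_reference(
        config.n_cell_types, config.n_background_probes, seed=SEED,
        cell_types=DEFAULT_CELL_TYPES,
    )
    es_models = cm.default_es_models(seed=SEED)
    beta, cohort, detp, annot, truth = cm.simulate_cohort(
        config, clock, reference, es_models
    )

    cio.write_matrix_tsv(beta, OUT / "beta.tsv")
    cio.write_sample_sheet(cohort, OUT / "sample_sheet.csv")
    cio.write_annotation(annot, OUT / "annotation.csv")
    cio.write_matrix_tsv(detp, OUT / "detection_p.tsv")
    cio.write_ground_truth(truth, OUT / "ground_truth.json")
    from cordmeth.clocks import write_clock_csv
    from cordmeth.deconv import write_reference_csv
    from cordmeth.scores import write_es_csv
    write_clock_csv(clock, OUT / "clock.csv")
    write_reference_csv(reference, OUT / "reference.csv")
    write_es_csv(es_models, OUT / "es_panels.csv")

    print(f"cohort: {beta.shape[0]} probes x {beta.shape[1]} samples -> {OUT}")
    print(f"planted deceleration: {truth.true_group_effect} weeks")
    print(f"planted ES shifts: {truth.true_es_shift}")
    print(f"BDNF model (intercept, slope, sd): {truth.true_bdnf_params}")


if __name__ == "__main__":
    main()
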
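import pytest

import matepref as mp


@pytest.fixture(scope="session")
def small_trials():
    """4x4-line factorial table, 5 matings/cell, moderate noise."""
    design = mp.DesignConfig(n_male_lines=4, n_female_lines=4,
                             min_matings_per_cell=5, max_trials_per_cell=15,
                             noise_sd=0.5, seed=11)
    effects = mp.line_effects_from_population(
        design, mp.PopulationSpec.open_ended(seed=11))
    return mp.generate_trials(design, effects)


from matepref.studies import null_line_effects  # noqa: F401  (shared fixture helper)
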
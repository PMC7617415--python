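from hypothesis import settings

# Reproducible property tests: same example sequence in every environment.
settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
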
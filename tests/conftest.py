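import hypothesis
from hypothesis import strategies as st

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")

#: standard residues only (no ambiguity codes) — most property tests use this
STANDARD = "ACDEFGHIKLMNPQRSTVWY"

protein_sequences = st.text(alphabet=STANDARD, min_size=1, max_size=60)
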
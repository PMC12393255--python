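You are combining per-topic summaries of a biomedical researcher's
publications into one final narrative research-interest profile, written in
the third person like a faculty-page biography.

Example summaries:
{example_input}

Example profile:
{example_output}

Now combine the following topic summaries for {researcher}.
<<<MATERIAL
{material}
MATERIAL>>>
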
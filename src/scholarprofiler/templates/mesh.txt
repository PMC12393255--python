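You are writing a narrative research-interest profile for a biomedical
researcher. You are given the MeSH keywords of their recent publications,
split into a methodology group and a health-domain group. Summarize each
domain separately, then weave them into a short third-person profile.

Example keywords:
{example_input}

Example profile:
{example_output}

Now write the profile for {researcher} from these keywords.
<<<MATERIAL
{material}
MATERIAL>>>
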
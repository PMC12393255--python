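You are condensing a group of topically related publication abstracts by one
biomedical researcher into one succinct paragraph describing the line of work.

Example abstracts:
{example_input}

Example summary:
{example_output}

Now condense the following abstracts for {researcher}.
<<<MATERIAL
{material}
MATERIAL>>>
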
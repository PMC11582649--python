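# Few-shot user prompt. Placeholders: {label_options}, {guidelines}
Classify a histology image tile. The possible labels are, in order:
{label_options}.
You will first be shown a sequence of labelled example tiles, cycling
through every label repeatedly. Closely compare the examples and extract
the visual features that distinguish the labels; then apply that knowledge
to the final, unlabelled target image.
Take a deep breath and adopt step-wise reasoning: architecture first,
cytology second, then weigh the candidate labels.
{guidelines}
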
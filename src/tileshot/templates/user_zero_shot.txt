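# Zero-shot user prompt. Placeholders: {label_options}, {guidelines}
Classify the histology image tile appended at the end of this message.
The possible labels are, in order: {label_options}.
Take a deep breath and adopt step-wise reasoning: first describe the
dominant tissue architecture, then the cellular morphology, then weigh
the candidate labels against each other before committing.
{guidelines}
Now thoroughly examine the appended image and reply with the JSON object
described in your instructions.
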
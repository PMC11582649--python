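This is the target image. Thoroughly examine it, compare it with the
examples above, and reply with the JSON object described in your
instructions.
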
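# keyword	role_id
transporter	143
permease	143
transport	143
ribosomal	158
kinase	130
protease	138
transcription	118
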
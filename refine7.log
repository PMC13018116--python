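python: can't open file '/root/pkg/refine7.py': [Errno 2] No such file or directory
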
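kL_EXT_EXT,kL_EXT_FLX,kL_FLX_FLX,kL_FLX_EXT,kF_EXT_EXT,kF_EXT_FLX,kF_FLX_FLX,kF_FLX_EXT,c_EXT,c_FLX
0.0,0.0,0.0,0.0,1.0,0.0,0.0,0.0,0.2,0.05
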
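label	total	n_neg	n_pos_normal	n_pos_glaucoma
b6d2f1	433	118	234	
c57bl6j	260		145	48
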
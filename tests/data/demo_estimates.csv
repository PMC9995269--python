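median,rel_median,se,n,p_t,p_mw,boot_se,scale,region,category,season,label
-0.2708428222163434,-0.27299531955007633,0.21047263746359865,307,4.143107147486598e-18,8.374999254055785e-18,0.024092539952532587,0.05,,satellite,annual,x1:5yr
-0.2524156522446833,-0.25382424131004794,0.08346973860684119,99,1.8653605442924046e-09,1.3848185264211474e-08,0.028013280673557767,0.10000000000000009,,satellite,annual,x2:5yr
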
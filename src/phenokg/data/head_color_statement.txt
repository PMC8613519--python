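has part some ( head and ((not ( clypeus )) and (not ( mandible and ((((not ( antenna )) and ( bearer of some red )) and (not ( labial palp ))) and (not ( maxillary palp )))))) and ( has part some ( labial palp and ( bearer of some yellow ))) and ( has part some ( mandible and ( bearer of some yellow ))) and ( has part some ( maxillary palp and ( bearer of some yellow ))) and ( has part some ( occiput and ( bearer of some dark brown ))) and ( has part some ( pedicel and ( bearer of some yellow ))) and ( has part some ( postgena and ( bearer of some dark brown ))) and ( has part some ( scape and ( bearer of some yellow ))) and ( has part some ( vertex and ( bearer of some dark brown ))) and ( has part some ( first flagellomere and ( bearer of some yellow ))) and ( has part some ( second flagellomere and ( bearer of some yellow ))) and ( has part some ( fifth flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some sixth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( third flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some fourth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( fourth flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some fifth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( sixth flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some seventh flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( seventh flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some eighth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( eighth flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some ninth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( ninth flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some tenth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( eleventh flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some twelfth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( twelfth flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some thirteenth flagellomere )))) and ( bearer of some light brown ))) and ( has part some ( thirteenth flagellomere and (( bearer of some color brightness ) and ( increased in magnitude relative to some ( color brightness and ( inheres in some flagellomere 14 )))) and ( bearer of some light brown ))))
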
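"""Frozen synthetic exemplar sequences backing the packaged seed/marker panels.

Every sequence here is a synthetic stand-in: a fixed pseudo-random protein
with realistic length and residue composition for its family (regulators,
minimal-PKS subunits, cyclase subfamilies, tailoring enzymes).  They carry no
biological homology signal beyond what the cohort generator plants by mutating
copies of them, which is exactly what makes planted-element recovery testable.
Generated once from a seeded RNG and frozen; do not edit by hand.
"""

_OVMZ = (
    "MQAGDKASGTYAVSKENTSEISSDSLAARNAHAIFKDESPPDMEATIFSGFTVFQLMWKK"
    "VSLIVITHSDAPEWEIASFGQGREQPLPEDGKRGPCRFTIFLMLNANCIDFFTAFTKRNV"
    "ASSCASADIYTEIQPAAEELKAGKTLEGNGGLPISTMFSVLTGKFTTILSISTREWVSCE"
    "KESPDFLLPMAIAGSLGREYGPQEHLVSHEAGE"
)

_OVMW = (
    "MTVITQLDDCLKEAYAMFEAFLALVLLKCSVKSTGKKKDGTNRMANPLPTVKLVQADGNL"
    "PFAMKLSYPSRPKYSVYP"
)

_MERR_OUTGROUP = (
    "MAKSSAKEVKVGDAQDPERLLGFSIPVRSEAEARVMAFYGSRLGLVLQNAHVEGNDSEGS"
    "YVIENSFSDFNTGVIYMYDNPVCMGDMPLGTVPDYEMLGTPGASDQNGTRPLFAAEGKML"
    "EEQSGIVYEA"
)

_KS_ALPHA = (
    "MQQQEIPTAVTGDKHIDPSAFHCRFDADASVTLAYLGQNDEVHTPGDLVANTDDMRQELS"
    "LAMGLPLLTASADLETGTVASEATTNASLLNQMASSGLRGWLLAIGNRATTDSGKQDLVE"
    "VSKASMNYKLVRCPQTLVNYGEYGYTFVAVTGQPSEPKKFRNVQSAFLFAKEQTKGAWVG"
    "VPQDRSALTELAYQVSQVTMGDAGRQHLAFARYLPVRRAVSHHLPGESASSAEYLTYTVS"
    "VVDIVFAILKEELFHDGVERDDGMYKVQSTLFSLMRTVFDETSLNRVTTLMLAMINKHGS"
    "ASTGSLISALAILEERYEDFNNSHFKQRTVITLVKRCWGPHDHDGAGTRIIQGNADVTGK"
    "KVDKRINKKKDNSLAHTALKLFEADTFGASEVGAGLPILARGALRTVFILSWVSITHVNL"
    "NAL"
)

_CLF_ANCESTOR = (
    "MIVRQLDEAGLGMILASEINSDLARKNEVNADENERPILKREADIHHRALMAVIQDLVYS"
    "ETEAENNVEMWALVDNVAVEELKGDLRIITDPKLKSVDAIGGTEVAQPARSFHFASKARR"
    "GTCRTASSLSLQRLVHQLRDELTAVDSLMLDRFVQVTAVVTEARATQVENHSFGIALTRL"
    "PVNIQKLRSNEAGRGYIAARQESNFNLSPNEILPLGWGTAKSCIFHDATNCVHGARSGND"
    "LKIVLSITADSEKLKNRFQEKVTIIGIYKLSDASSSVFPIGTTACEIATVGWALDKPVFL"
    "ARSALAVELCSKAKLGALQKLRSLRQAMPRKESQREVTNRAARQETVPGRTVDIPAMTTG"
    "HTGVEWELTFVYVWRQYSKPLRTGDEKEGTELSADRTSIILRL"
)

_ACP = (
    "MILLPPCLLCLLDTKVIVKSEGFMRQTEEMQDLHRLRRELDCFIYQNSFTKENFSEDSTQ"
    "CSVPLTAGHTEGCGFRPIHDGWERK"
)

_TCMN_N = (
    "MTGEARMVLLRNKTMGSAFAYSEPNGRRGMNQEPFRLWAADYGHGVLIQKGSVLALMTYG"
    "AFQDALSSGFIFYPRDTDLLAQDIDASRLGQEFYMIRHLLTVAQRPIKCIRNVGGVECVL"
    "TAILVWQDQVSTLYVKHQGIRRIRHLEAEGAQSVSKVVIV"
)

_TCMN_C = (
    "MGRKMGPETDVAEGDGPTTKFETYQEKPLCKKETQVYRSHGNHGPQQMQLGCVVSRVECD"
    "VDGLDSSLKINKPSKRLQDRVTGHTQTTAQPRALKQDVKPADTVPKRELELDRDDNSTIV"
    "YIRDKDVDEMLRQGNELLSSHIVGDSIIKRDPIDHGGLHG"
)

_TCMI = (
    "MLIASLDQIPWLTEADLELEEREPLQQNARKNGQLELFAQTSGRQTSVRLGAVLIMSNAG"
    "NGIKVPVRKSAADGELEGLLAVKKYSAPDVIRVMQEFPQPTTTFINSD"
)

_TCMJ = (
    "MGELGTLLKGRALLLPQASRLNPSMVFPTLERPYAAGVDQQSLELQEVEKVGRLSPAIKG"
    "KCANSALIKDKCAGSIPFITLAYTPMGCLDIERRPDEAVLVSLATELYKL"
)

_OXYN = (
    "MRNPLRDKTADAAVDLVKPTTHHYLSTMAECDSAYTFALADADGRDLITMCKDRIAQALL"
    "FRQVIGGEMFMERILLSALIGVATCLNDDKPRKVDGIASLATQRKVFYKEPKTSHPILGS"
)

_SNOAL = (
    "MGLVFYFLNKNADDMMWVEIVDIVTATRCNLPTLRVTVSSGDLAILKEVIILRHLFAKMG"
    "RHSLKAILVSDIPTSKQTAVANVIKKGAGDSQFIQSVIRPQVAGKLKDIQPPKWEKGLHV"
    "GRKSPKCPKEKKKADAKMPF"
)

_GT = (
    "MAIIQVDGLYEESFCMGPLSEWRASHASISTEEAKPPASYLLAIRMLLDPEYTGVLVKAS"
    "VNHAQADINVAWCEQVTFENYHYFCKLSRHYGDQKGQITVGSRIFYMGRLNLLLVPDVMD"
    "QFFFEDDGSASDVRNLASKPDGKRQPVEESGRDDAVEAARQKLDPKASGNENTALSSSFT"
    "HVAEELGGGTKVALSYPRTDTVAAPEARIMLPWTAAKTVALIVTPWQLIDEIKQIIFSWG"
    "STSAVGMLNIISRDLMGHTTYSGSIGQLITRRRQIVVMASGLGGSMIEDDKTKSQQGVRL"
    "IHVTCNCVEMGDIKAFPVKEENYVKTATPGGHNTRQAKGLDEHKRDSHKGIKQAQNFGIK"
    "LQLVCNKAKPLLLYLSYGRLLEIVKVVDIEKRSYDRLWHQ"
)

_KR = (
    "MALGSDIERWLIGKQLKRRVGPATMYVGREFGPQAQTEPTLARQGLYTEFKFMVEAAVLS"
    "KISQYAVNIKMVASQTPNTNGLLVHICGIREYGIVAAYHFMRYESLFTLRICSPTTKLSA"
    "FSFEKFLAGGHLKEPKIIQSANAPLFSSEIEVVLDNGEFDSTKIRMGDLQILMLVPEKSY"
    "FLIAEKAQRTNLEPSSAARCRRIAEKDVSATVGSGCEALTREEKVVHKDPSESQLALAYS"
    "GTNTKEQNAILQIKSHLARTSDKLAYSGVETGILHLRLQGIDA"
)

_OXYGENASE = (
    "MSTVALLQHSRRGSVYVRESEGPFACVFIAQQLTFLFGQGCLFCFANKYIMYTGMMLMLS"
    "IQLQELVNLEDAEGEAELGLGILQTVRNSTSEEHAKLDLAPKAPVVTLPHGGEIYESAYA"
    "HVLFLQKQFRDSIIVETGLPTMYRCTAKGATPMRTGYILGMDFFEQDTGFAQTEGLFRLL"
    "GARDLMQYSPDFGGKYKKTGAVHSVRSLKKMEGLIVMERTLVACYFCTEWGICEQCQNDH"
    "LRGVLDEIGPTRRELVDFAEFDGNRYPQAEHSQGDSKAGVHTSTISDVGQPIHAGHAGIV"
    "RDVSKLDLISPAGMRTGQRLKSVLADAGILYAVGIILRPWMAGLLAFNASGVFGRKLANL"
    "ENEISETEAKEACSQTCTLITTANSYLVLALWQTTLDYESEAARQPAEHLKSCEFWSIED"
    "GMDDSFSSTQDALHVTKGKCNLVLGVAGRMQGVDVSLLPGLAQRSLGFPGFNNGCSTETT"
    "IPRNSHTLQYS"
)

_KS_TYPE3 = (
    "MYVLVSSSDENTWNGYFTPVVVSEMGIDGASNLKHLIQFKRVVFSEVSAIYAALDVNLEI"
    "LLSNNFFVNDVCGRLKRAVLVEGKIHQDDYAYREQGPFETKHRAGYIEIRIEYTGVATGK"
    "VQIAFQVGQNLPGNPGGVMTKKVPCTFIPLHREVKEWSNNNSLLCQTTTESDTKVLDARL"
    "DGNEREILEPLSLLDAFANHEPINKLYVGRLLKQTDAELKPELLVGSKAVKTFILKLTDE"
    "VEPDFHAYVGQEAEILGRRRIDPFRAQDKGIRQILKVNTASSVRTYRVNFVALRYGDMKG"
    "IGFGRECDAMQRLLNYEDVGRPFGIHEGIDRKIITQPEKRVPVASNLAIKGKPQNSHAKM"
)

_TERPENE_CYCLASE = (
    "MAEVLNILAGRKSEVPMLRSDDCKLNLSLAVGRQITGYNPFNLPDVARIVAVDFEEAQFL"
    "HVPANKNLYVMLEGNFLSTYHNDDFLPVEPYAGGLFVPMSDVPDVGMERKGKVRPESLLE"
    "ANARKLGSHLGKAPDAYIDHPILEIVEEKVQVNRANGIRVSILAAVGSTFEISVGRVLMQ"
    "MLRDSKMWKQPNRIRYRRVIHPLAASAMMLIEIIVRSFAAKVTTGLEDATDPRTAQTIQT"
    "RVVDDLQHHTELFEIELILTIIRAVLDRVFRLNTRRGGRMSLKKVLALDNLTVGKRCMGD"
    "DDEINKELSYNPLELKSTLIQSYPGSPAFL"
)

_NRPS_C = (
    "MITKISSEWKIEGYSPGHGTIQDTQGSTTLGLGQIPQVWTIVRQGPFVCAHQQLASSFSL"
    "HVLAENGDFAICWCRLFSLYAVRKDGMIKTNTCTVAARVLAVKVFTEKLLLANFDSTYFK"
    "KIMRQFGRSPYLMTPLVPESYGMKYQGTAVGPEGLAYLVISPPYPVIRGHCARFHLLEVG"
    "PGVPVSGKLKKERKLRRFRQGVCFLYAAAGVIAPHLPTLNCGPNILVAQQALRVFITGLG"
    "CFNPVPLSSSGLCAQFVEKHGDNKSATDDPHMLVSTEFDIKEGNVKAAADRFLSLWSLKE"
    "VDESRPLVFDEITPDTTMSPLIFNGIIFIIVLESLDGDYLVPIDSAKGLKQGSQMQQVRK"
    "EKVANCSLGHTTSSRDKNPEPVFQEEDEGIKYSDYPSRVKLPSEIRQDSWKGEQKKPERL"
    "GFGEDETIKLTWFQTKLFNVTYMSQSYYTF"
)

_CLF_REFERENCE_DATA = [
    ("CLF_oviedomycin", "oviedomycin", "angucycline", (
        "MIVLILDEDGLKMALGSEIPSDGARDNEVNADENERPIPSREALGAHKVLMAVITAMVYS"
        "CTERSNNVEMLALVDNCAVAQLSGDLRMITDPKLKSVTWIGGTEVATPARSFHFAQKANR"
        "KTYRRAKSLSLRRLDHQLRDFVTCVDSLMLDRFSQQTVVVTEARATPVENHSFGIGHIRL"
        "PENRQACRSQEAGRSYIAARQESNFVCSPNEILYLSWKTAVMCIFHDATNCVCTAPSNNN"
        "LKAVRMITQDSETLNNRCQHKYTNPGIYKLSDARSPVFPQGATACQIALVGWCMDKMFYL"
        "ARSYMRMELESAAKHQAPRKMRSLRTAMPRKTDQREVGVLDEKQETVCGRTVDIPGMTRG"
        "HTEVENELTYVYVWRQQSKPCRNIDEKEAYEISRDRTIIILRL"
)),
    ("CLF_PD116740", "angucyclinone PD116740", "angucycline", (
        "LIDRFLDQIGLGMIEASEIVRDLARKNEGNYHENERPILKRPAWIHHQALFQVKADLVWS"
        "HTEAECNIEMWAVVDRKALCCNKGKGRIITLGKYKSADAVGGTEVAQPARSLHFASKAKR"
        "KTTRTCSSKQLMRLVHQLRDCLTAVDSLNLCRAVNVTAVVTEQRAHNVEYHGFGIQLCRA"
        "PVGILKLRQNEKDRGFLATRPESDFNWSPREILPIDWGTAKSCIFYDATMCIMGAPHGNA"
        "KKINLSITIDSEKRKNRFQEKKTIIGIYHLYDECSKVFPIGTTACENATVGTANDRPHFL"
        "NNSYLAVLLCRKWHYIALQKGRILRQKMPCKEKWRVVTNRAAYQETVRYRTKQIPAMTTG"
        "HPGEEWSLTFVYVLEDYSKPPRTGAEKEGYELIADRTFDIIRL"
)),
    ("CLF_hydroxyfujianmycin", "hydroxyfujianmycin", "angucycline", (
        "MIVRQTHRAGLFSDLAGEIKIDLPSKPEVGYDEVERPILSRETDIHIRALWAVIRDTVYC"
        "ETEACNNSYFGALMDNVAVHGLAGKLRIDYDEKNVWVDATVGCEVIQPERSFHFALQPRR"
        "GTFRTNSSCSLQGEKHQIRDLLTAVGFLMLDIFRQVTDVVTELPARQFYGMSQGMALPYF"
        "PPNINKLDHNEAGPGMIAAAQEFNFDASPNEALGFGWGRAKFWIFHDATNCVHGAPSCND"
        "LKIVEMITSCHVKLKNSDTENVTIIGIYKLSDALSSVCPIGTGSCYIATVCWHLHQLVFT"
        "DRSAHAYELWYKCWSGALQKLGSLRQGDPRSESQREWTNRAYNMETVPGRTDRFEAMTDG"
        "HTYVEWELTFDREWNQYSKPLRTSDQKEGTELSADSTSQKMRL"
)),
    ("CLF_landomycin", "landomycin", "angucycline", (
        "MIVNNLDEDGLGMILASERHSCKARKNECNAHENERPILKQEAQVYHRALIVVIQDLVYM"
        "ENEAENDVEMWALVDNVAVEFQDGDLRIIHDPKKKSVNTIGDTQVAQTAVSFHFRIDQSR"
        "GTEFTASSHSLQMTSHMLADEPTAVNSLMLDFFVQGDAEHYYARATKVHNHQFGGALTDE"
        "PVNIQKLRSNEAGRRYIAVWDTSNFNLFGLMILGLGWGTAKSHIFHDATNCVHGIMSENE"
        "LKIVCSITAMEEKLKNRALEKDTIIGILKDSPYHTTQSPIGTTAVETACVGWALDKPAQL"
        "ANQALATIWCPKNKLGAMQRLRNLRQAGPTKPRQREVTNRVASQETVNGRTVDIKAMTWV"
        "HTFYENMLPFIYVWRQWSKTLCTYDEWEVWELSADKTMIILRL"
)),
    ("CLF_frigocyclinone", "frigocyclinone", "angucycline", (
        "GEVKCVDEIVLPNILASEINSDLARKNEWNADENERPILKREDDIHHRYLDMAIQQECYL"
        "ETEAINHVEMNALVINWAVPELKGDMRIYTQPKWKSVRAMGGTEVPQPARYRNNASKAFG"
        "GTFRIASSLSHFNKFHQHVDELVAQDTLMLDAFVIGTAMVTYWRATQVMNHSFGIALRQL"
        "DVNIQECARNEAFRGEIAADQESNFGLSLNEILPLGWGPTKSGNFHDATNELAAERSGND"
        "RQIVLYKTDDDEKLKSRFQEAVECIGFYKPSQASISVSPIGTVACSAVTVGRYLDKPVGL"
        "ARFALAVELHMKNKLGASQKLRSLAQAMPRLESQREVQNRKADQEPLALRTVDLPAMTTG"
        "HPKVEWASTFEYPWRWYSAPLRTGDEYEWTHYFQDRTSIILRL"
)),
    ("CLF_balmoralmycin", "balmoralmycin", "angucycline", (
        "MISRSLDIAGMGMIVASNINSDQAQTNWVNADEHERPLTKQNAFIVHRALMAVIQALVYS"
        "ETEAENNVEMWIPVDNVRVEGLKGDYRIITLQKLKLVDAIGGTEVAQPARQFEFASKARH"
        "GTNATASESSLSLLVNQLRDEITAKASLRLDFVVQVYAVVSGARRTQVERHKFGIALVIL"
        "PINIFKLRSNEGPRGYCAYRQESNFNYSPNEILPLGWGTAKSCIFHDATNCVMGARSCED"
        "LKLVLSIFADSEDLFNRFQEKVCIPGISKITYASTTVFPVGDTCCDIATMGWMLNKPVFL"
        "IRSALIWELCSKAKLTALEKTRSLRQAMPRKEYQREAHHFSARQITVPGRTVDSVAMTTG"
        "MHGVENELHFYYVWRQKSKPCATTDEKEGTDNSRDRTSMILLL"
)),
    ("CLF_urdamycin", "urdamycin", "angucycline", (
        "RIIRQIDPAGEGMQLASKINHDLARKNEVYADENEKPDLKREADIFHRAIMAHAQDLNWS"
        "HTEAENNVEMWALNDNVLVEGLAGDLAIITRPVLVSHDAIGGTEEYFWCRFFHFAALNRF"
        "ITCRTAPSLCLLHLEHRLRDELTKVDSLMLDEFVQVTAVVWEAPVTQVENFSFEAALTRL"
        "PCNWKDLRSLEYGEGYIASRQESRFNSDPNELLPIRWGTLKSCIFHDLWYCVHGAFGGND"
        "LIKVLHITADSNKHKNRFQEKVCWIGIYWLSDEQSSVFQIDTAACEIATLGKALDKPWFL"
        "HRSALFCELCMEKKLYALQGLHFKRQAMPRKEAQVTVTNWATKQITVPGKTVDIPQPTTA"
        "HTGVDKELTFAYVWRQYSNGLRTGSEKEGYELSADRTSIILRF"
)),
    ("CLF_gaudimycin", "gaudimycin", "angucycline", (
        "MIERQLMEAGLGMILAEEINHDHENVNEVPAYELERPILKREADTHHRFIHAVIQILVYS"
        "ETEAMNPFFDWALVMYNAVWRLKGPMFIPTDYKLKSGDAGGGTVVSKPARSFHFASKAPR"
        "GTITTPSSLSLQRLVHQYFDELHAVDWKPLDREVFQTYVVTSAPAVQVENFSFGIALTRL"
        "PVNIQKLTSNEAGRGYIAARQEANFRPHPNSILPLGPGTAKSCIFHDWANCRHVARQGND"
        "LKIVLPQTADSHLLKNRFQTKVTIIRIYILSDASSSVCAHVTTACEIATVGWALTKPCFL"
        "ARMAEAVELFSTAKLGAAQKLNSLRCAMWRKLSFREVTNRAARDETVPWRTVDHPAMTMC"
        "HDGDCWELTFVYVFRQYWKPRRTGDEKEGLEESADRTSIILRL"
)),
    ("CLF_tetracenomycin", "tetracenomycin", "tetracenomycin", (
        "MHVAQLDEAVLGMIYMSEINGDVFWTNEVSAHDNEHPILKRECDMHHRAVHSVISDCVHS"
        "EMPAERWFYMCAPVDHVAVESLKGNLRIITHPKLKVVDAIRMTCQAQCARSVHFASKARR"
        "GHCMTCSGASLCRLVSQLRDELTAVDSRMFDRVVQVTPVVTEPHATFVENDCFGIALRRL"
        "PVNIHKLRSNEAGRGYIAARGQLHQNLSSDEILRNGFGTAKSCIFHDGTAYVHGRRSGND"
        "LKIVLSITADDQGLCNGFQNIVTCICIYKLCDASSSFFPIMLTACEIALVGWALQNPVYL"
        "ATSLETVEMHQKGMSGAKQKHRSDRQCMPFKESQYEVTNIWANVEGVPGTGVDISLMTTG"
        "HTGRYCKYTFVYGWRLYSKPLKTHGELECTELSAARKSIIPRL"
)),
    ("CLF_nogalamycin", "nogalamycin", "anthracycline", (
        "MIVTQLQELGLGPILASEINSDWAHKNEQNWNHYEEPALKREIDIHHRALMWPIQDLWYN"
        "RTEAPNNVEMWALVRNVAVNELKGTLRIIMDPLLKSHDFIIGLCVAQPARMFHFSMKAVR"
        "GTTRQASSLSLQRVVFLLRWLLTAVDSIMSDRIVQVTAVVTEASLTQVENHSDGIAYTRL"
        "YIGQQKLGLNEAGRGYDLARQESCFNLSPNEIHPLGWETAKSCIFADATWCVAGAVSING"
        "IIFVLCRMWDCEKLKSRHQEKPTIAGGYKLDDASSSPFPIGTTECEIATCGWLLCFPPFL"
        "APSDLAKELCLAAKLKAGPKLRSLRWAMHRKESVQSQTNEAARQETVEGRTNGIPAHTTG"
        "HMCVETELAFVEVWRQYSKQLRYHFEKEGTELSMMETSIILRL"
)),
]
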